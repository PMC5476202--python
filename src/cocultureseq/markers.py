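"""Absolute qPCR quantification, mixture/read-yield prediction and
gDNA-based biomass estimation.

Standard curves are log-linear, Ct = b + m*log10(copies), fitted by least
squares on a dilution series; the amplification efficiency is
E = 10^(-1/m) - 1 (E = 1 is perfect doubling per cycle). Species-specific
rRNA-marker copies act as a proxy for each species' share of total RNA:
shares predict the split of sequencing reads among species in a mixed
sample. Single-copy-locus gDNA quantification against dry-weight standards
estimates mycelial biomass per species, scaled from the extracted aliquot
to the whole flask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

DEFAULT_DILUTION_FACTOR = 500.0


class StandardCurve(BaseEstimator, RegressorMixin):
    """Least-squares Ct-versus-log10(copies) calibration line.

    Fitted attributes: ``slope_`` (Ct per log10 copies, negative for an
    amplifying assay), ``intercept_`` (Ct at one copy), ``efficiency_``,
    ``r2_`` and ``range_`` (dynamic range in copies). Below-detection wells
    (NaN Ct) are excluded from the fit.
    """

    def fit(self, copies, ct):
        copies = np.asarray(copies, dtype=float)
        ct = np.asarray(ct, dtype=float)
        ok = np.isfinite(ct)
        copies, ct = copies[ok], ct[ok]
        if (copies <= 0).any():
            raise ValueError("standard copies must be > 0")
        if len(np.unique(copies)) < 2:
            raise ValueError("need >= 2 distinct copy levels to fit a curve")
        x = np.log10(copies)
        res = stats.linregress(x, ct)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r2_ = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
        self.efficiency_ = float(10 ** (-1.0 / self.slope_) - 1.0) if self.slope_ != 0 else np.inf
        self.range_ = (float(copies.min()), float(copies.max()))
        if self.slope_ >= 0:
            warnings.warn("fitted slope is non-negative; not an amplifying assay")
        return self

    def predict(self, copies) -> np.ndarray:
        copies = np.asarray(copies, dtype=float)
        return self.intercept_ + self.slope_ * np.log10(copies)

    def to_copies(self, ct, flag_range: bool = True):
        """Invert Ct to absolute copies; NaN Ct reports below-detection.

        Returns (copies, flags) where flags is one of '', 'below_detection',
        'out_of_range'.
        """
        ct = np.asarray(ct, dtype=float)
        scalar = ct.ndim == 0
        ct = np.atleast_1d(ct)
        copies = np.where(np.isfinite(ct), 10 ** ((ct - self.intercept_) / self.slope_), np.nan)
        flags = np.full(ct.shape, "", dtype=object)
        flags[~np.isfinite(ct)] = "below_detection"
        if flag_range:
            lo, hi = self.range_
            out = np.isfinite(ct) & ((copies < lo) | (copies > hi))
            flags[out] = "out_of_range"
        if scalar:
            return float(copies[0]), str(flags[0])
        return copies, flags


def fit_standard_curve(copies, ct) -> StandardCurve:
    return StandardCurve().fit(copies, ct)


def ct_to_copies(ct, curve: StandardCurve):
    return curve.to_copies(ct)


class LinearCurve(BaseEstimator, RegressorMixin):
    """Plain linear calibration, signal = a + b * amount (plate-reader assays)."""

    def fit(self, amount, signal):
        amount = np.asarray(amount, dtype=float)
        signal = np.asarray(signal, dtype=float)
        if len(np.unique(amount)) < 2:
            raise ValueError("need >= 2 distinct standard amounts")
        res = stats.linregress(amount, signal)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r2_ = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
        return self

    def predict(self, amount) -> np.ndarray:
        return self.intercept_ + self.slope_ * np.asarray(amount, dtype=float)

    def to_amount(self, signal) -> np.ndarray:
        if getattr(self, "slope_", 0) == 0:
            raise ValueError("degenerate calibration (zero slope)")
        return (np.asarray(signal, dtype=float) - self.intercept_) / self.slope_


@dataclass
class MixtureEstimate:
    """Per-species marker copies, shares and predicted read yield."""

    copies: dict[str, float]
    shares: dict[str, float]
    predicted_reads: dict[str, float] | None = None
    ratios: dict[tuple[str, str], float] = field(default_factory=dict)


def mixture_shares(copies: dict[str, float], planned_total_reads: float | None = None) -> MixtureEstimate:
    """Marker-copy shares per species and the implied read-yield split."""
    if any(c < 0 for c in copies.values()):
        raise ValueError("copies must be >= 0")
    total = sum(copies.values())
    if total <= 0:
        raise ValueError("all species have zero marker copies")
    shares = {sp: c / total for sp, c in copies.items()}
    predicted = None
    if planned_total_reads is not None:
        predicted = {sp: share * planned_total_reads for sp, share in shares.items()}
    ratios = {}
    for a in copies:
        for b in copies:
            if a != b and copies[b] > 0:
                ratios[(a, b)] = copies[a] / copies[b]
    return MixtureEstimate(dict(copies), shares, predicted, ratios)


def ratio_fold_change(earlier: MixtureEstimate, later: MixtureEstimate) -> dict[tuple[str, str], float]:
    """Fold change of pairwise marker ratios between two time points."""
    out = {}
    for pair, r0 in earlier.ratios.items():
        if pair in later.ratios and r0 > 0:
            out[pair] = later.ratios[pair] / r0
    return out


@dataclass
class BiomassEstimate:
    aliquot_mg: float
    flask_mg: float
    ct: float
    flag: str = ""
    gdna_copies: float | None = None


class BiomassEstimator(BaseEstimator):
    """Dry-weight estimation from single-copy-locus qPCR.

    Fit on standards of known freeze-dried mycelium weight (the emulated
    protocol spans 2-50 mg); because standards and samples are measured on
    the same gDNA dilution (default 1/500) the dilution cancels in weight
    units and is retained only to report absolute locus copies.
    """

    def __init__(self, dilution_factor: float = DEFAULT_DILUTION_FACTOR,
                 copies_per_mg: float | None = None):
        self.dilution_factor = dilution_factor
        self.copies_per_mg = copies_per_mg

    def fit(self, standard_mg, standard_ct):
        self.curve_ = StandardCurve().fit(standard_mg, standard_ct)
        return self

    def estimate(self, ct: float, aliquot_fraction: float = 1.0) -> BiomassEstimate:
        if not (0 < aliquot_fraction <= 1):
            raise ValueError("aliquot_fraction must be in (0, 1]")
        mg, flag = self.curve_.to_copies(ct)
        copies = None
        if self.copies_per_mg is not None and np.isfinite(mg):
            # the measured well held copies/dilution_factor; report the undiluted extract
            copies = mg * self.copies_per_mg
        return BiomassEstimate(
            aliquot_mg=mg,
            flask_mg=mg / aliquot_fraction if np.isfinite(mg) else np.nan,
            ct=float(ct) if np.isfinite(ct) else np.nan,
            flag=flag,
            gdna_copies=copies,
        )


def estimate_biomass(ct, biomass_curve: BiomassEstimator | StandardCurve,
                     dilution_factor: float = DEFAULT_DILUTION_FACTOR,
                     aliquot_fraction: float = 1.0) -> BiomassEstimate:
    if isinstance(biomass_curve, StandardCurve):
        est = BiomassEstimator(dilution_factor=dilution_factor)
        est.curve_ = biomass_curve
        biomass_curve = est
    return biomass_curve.estimate(ct, aliquot_fraction=aliquot_fraction)


def normalize_to_rrna(target_abundance: float, rrna_abundance: float) -> float:
    """Transcript level normalised to the species-specific rRNA-marker abundance."""
    if rrna_abundance <= 0:
        raise ValueError("rRNA abundance must be > 0")
    return target_abundance / rrna_abundance


def squared_pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, _ = stats.pearsonr(x, y)
    return float(r**2)
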