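"""Synthetic qPCR plates and gDNA biomass samples.

The Ct model is log-linear: Ct = intercept + slope * log10(copies) + noise,
the behaviour of an efficient TaqMan-style assay over its dynamic range.
Standards default to the plasmid dilution scheme of the emulated study:
ten five-fold dilutions starting at 5e7 target copies. Off-target or
zero-copy wells report no amplification (NaN Ct).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PERFECT_SLOPE = -1.0 / np.log10(2.0)  # -3.3219...: exact doubling per cycle


@dataclass(frozen=True)
class CtCurveParams:
    """True underlying Ct response used by the simulator."""

    slope: float = PERFECT_SLOPE
    intercept: float = 40.0

    def ct(self, copies) -> np.ndarray:
        copies = np.asarray(copies, dtype=float)
        with np.errstate(divide="ignore"):
            out = self.intercept + self.slope * np.log10(copies)
        return np.where(copies > 0, out, np.nan)


def default_standard_copies(n_dilutions: int = 10, start: float = 5e7, step: float = 5.0) -> np.ndarray:
    """Ten five-fold dilutions from 5e7 copies, the default standard series."""
    return start / step ** np.arange(n_dilutions)


def simulate_standard_series(
    curve: CtCurveParams = CtCurveParams(),
    noise_sd: float = 0.0,
    seed: int | None = None,
    copies: np.ndarray | None = None,
) -> pd.DataFrame:
    if copies is None:
        copies = default_standard_copies()
    rng = np.random.default_rng(seed)
    ct = curve.ct(copies)
    if noise_sd > 0:
        ct = ct + rng.normal(0.0, noise_sd, size=len(copies))
    return pd.DataFrame({"copies": copies, "ct": ct})


def simulate_qpcr_plate(
    targets: list[str],
    true_copies: dict[str, dict[str, float]],
    curve_params: dict[str, CtCurveParams] | CtCurveParams = CtCurveParams(),
    noise_sd: float = 0.0,
    seed: int | None = None,
    cross_reactivity: dict[tuple[str, str], bool] | None = None,
) -> pd.DataFrame:
    """Simulate sample wells for species-specific assays.

    ``true_copies`` maps sample -> {species: copies}. Each assay (one per
    target species) amplifies only its own species unless the boolean
    ``cross_reactivity[(assay, species)]`` says otherwise; non-amplifying
    wells get a NaN Ct (no-amplification sentinel).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sample, copies_by_species in true_copies.items():
        for assay in targets:
            amplified = 0.0
            for sp, copies in copies_by_species.items():
                reacts = sp == assay or (cross_reactivity or {}).get((assay, sp), False)
                if reacts:
                    amplified += max(copies, 0.0)
            curve = curve_params[assay] if isinstance(curve_params, dict) else curve_params
            if amplified <= 0:
                ct = np.nan
            else:
                ct = float(curve.ct(amplified))
                if noise_sd > 0:
                    ct += rng.normal(0.0, noise_sd)
            rows.append((sample, assay, amplified, ct))
    return pd.DataFrame(rows, columns=["sample", "assay", "true_copies", "ct"])


DEFAULT_GDNA_STANDARD_MG = (2.0, 5.0, 10.0, 20.0, 50.0)


@dataclass
class GdnaBiomassSim:
    standards: pd.DataFrame  # species, mg, ct
    samples: pd.DataFrame  # species, ct
    truth: dict[str, float]  # species -> flask dry weight (mg)
    copies_per_mg: float
    aliquot_fraction: float
    dilution_factor: float
    curve: CtCurveParams = field(default_factory=CtCurveParams)


def simulate_gdna_biomass(
    dry_weights_mg: dict[str, float],
    copies_per_mg: float = 2e5,
    aliquot_fraction: float = 1.0,
    seed: int | None = None,
    curve: CtCurveParams = CtCurveParams(),
    noise_sd: float = 0.0,
    dilution_factor: float = 500.0,
    standard_mg: tuple[float, ...] = DEFAULT_GDNA_STANDARD_MG,
) -> GdnaBiomassSim:
    """Simulate single-copy-locus qPCR for biomass estimation.

    Standards span known dry weights (default 2-50 mg); samples measure the
    aliquot of each species' mycelium (flask weight x aliquot fraction).
    Both are measured on a 1/500 dilution of the extracted gDNA, matching
    the emulated protocol.
    """
    if not (0 < aliquot_fraction <= 1):
        raise ValueError("aliquot_fraction must be in (0, 1]")
    if any(w < 0 for w in dry_weights_mg.values()):
        raise ValueError("dry weights must be >= 0")
    rng = np.random.default_rng(seed)

    def measure(mg: float) -> float:
        copies = mg * copies_per_mg / dilution_factor
        if copies <= 0:
            return np.nan
        ct = float(curve.ct(copies))
        return ct + rng.normal(0.0, noise_sd) if noise_sd > 0 else ct

    std_rows = [
        (sp, mg, measure(mg)) for sp in dry_weights_mg for mg in standard_mg
    ]
    sample_rows = [
        (sp, measure(w * aliquot_fraction)) for sp, w in dry_weights_mg.items()
    ]
    return GdnaBiomassSim(
        standards=pd.DataFrame(std_rows, columns=["species", "mg", "ct"]),
        samples=pd.DataFrame(sample_rows, columns=["species", "ct"]),
        truth=dict(dry_weights_mg),
        copies_per_mg=copies_per_mg,
        aliquot_fraction=aliquot_fraction,
        dilution_factor=dilution_factor,
        curve=curve,
    )
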