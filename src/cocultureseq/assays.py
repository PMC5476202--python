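"""Deterministic assay arithmetic: pNP activity rates and DNS sugar release.

pNP (para-nitrophenol) glycoside assays report activity in rho-mol pNP per
minute per microlitre of culture filtrate (default incubation 3 h). DNS
reducing-sugar assays are calibrated against glucose and corrected for the
reducing ends already present in the straw and filtrate controls; values
below background are reported negative with a flag, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markers import LinearCurve

DEFAULT_INCUBATION_MIN = 180.0  # 3 h


@dataclass(frozen=True)
class ActivityMeasurement:
    released_pnp_rho_mol: float
    minutes: float
    filtrate_ul: float

    @property
    def activity(self) -> float:
        return pnp_activity(self.released_pnp_rho_mol, self.minutes, self.filtrate_ul)


def pnp_activity(released_pnp_rho_mol: float, minutes: float = DEFAULT_INCUBATION_MIN,
                 filtrate_ul: float = 1.0) -> float:
    """Activity in rho-mol pNP / (min * ul filtrate)."""
    if minutes <= 0 or filtrate_ul <= 0:
        raise ValueError("incubation time and filtrate volume must be > 0")
    return released_pnp_rho_mol / (minutes * filtrate_ul)


@dataclass(frozen=True)
class SugarRelease:
    glucose_equivalents: float
    straw_control: float
    filtrate_control: float
    corrected: float
    below_background: bool


def dns_corrected_sugars(sample_signal: float, straw_ctrl_signal: float,
                         filtrate_ctrl_signal: float,
                         glucose_curve: LinearCurve | None = None) -> SugarRelease:
    """Background-corrected glucose-equivalent sugar release.

    Signals are converted through the fitted glucose standard curve (pass
    ``None`` if values are already in glucose equivalents), then both the
    straw and filtrate controls are subtracted.
    """
    if glucose_curve is None:
        conv = lambda v: float(v)
    else:
        if not hasattr(glucose_curve, "slope_"):
            raise ValueError("glucose standard curve is not fitted")
        conv = lambda v: float(glucose_curve.to_amount(v))
    sample = conv(sample_signal)
    straw = conv(straw_ctrl_signal)
    filtrate = conv(filtrate_ctrl_signal)
    corrected = sample - straw - filtrate
    return SugarRelease(sample, straw, filtrate, corrected, below_background=corrected < 0)


def per_biomass_release(amount: float, dry_weight_mg: float) -> float:
    """Released amount expressed per mg mycelial dry weight."""
    if dry_weight_mg <= 0:
        raise ValueError("dry weight must be > 0")
    return amount / dry_weight_mg
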