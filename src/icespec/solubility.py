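"""Van't Hoff solubility modeling and nucleation-regime classification.

The temperature dependence of a sparingly soluble organic compound is
described by the van't Hoff equation

    S(T) = S0 * exp(-ΔH_sol / (R T)),

with ``S`` in weight percent, ``T`` in kelvin, ``S0`` the
pre-exponential (hypothetical infinite-temperature) solubility and
``ΔH_sol`` the dissolution enthalpy.  For an aqueous solution of
density ρ (g/mL), ``C = S * 10 * ρ`` converts weight percent to mg/mL
(1 wt% = 10 mg/mL for water).

Whether a cooling droplet crosses its solubility curve within the
freezing range decides which nucleation pathway operates: solutions
that start supersaturated or become so on cooling precipitate crystals
that act as efficient ice nucleators, while undersaturated solutions
rely on dissolved-aggregate nucleation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GAS_CONSTANT",
    "VantHoffModel",
    "RegimeClassification",
    "PHLOROGLUCINOL_FIT",
    "solubility_at",
    "wt_to_concentration",
    "fit_vant_hoff",
    "classify_regime",
]

GAS_CONSTANT = 8.314462618  # J/(mol K)
KELVIN = 273.15


@dataclass(frozen=True)
class VantHoffModel:
    """Van't Hoff solubility law ``S(T) = S0 exp(-ΔH_sol / (R T))``."""

    s0_wt_pct: float
    dh_sol_J_per_mol: float
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        if self.s0_wt_pct <= 0:
            raise ValueError("S0 must be positive (wt%)")

    def solubility(self, t_kelvin: float | np.ndarray) -> float | np.ndarray:
        t = np.asarray(t_kelvin, dtype=float)
        if np.any(t <= 0):
            raise ValueError("temperature must be positive (kelvin)")
        out = self.s0_wt_pct * np.exp(
            -self.dh_sol_J_per_mol / (self.gas_constant * t)
        )
        return float(out) if out.ndim == 0 else out


#: Fit to literature solubility data for phloroglucinol in water.
PHLOROGLUCINOL_FIT = VantHoffModel(s0_wt_pct=7e7, dh_sol_J_per_mol=42460.0)


@dataclass(frozen=True)
class RegimeClassification:
    """Nucleation regime of a solution over its freezing range.

    ``supersaturated``: the concentration already exceeds saturation at
    the warm end of the range.  ``solubility-critical``: cooling drives
    the solution across the saturation curve inside the range, at
    ``crossing_temperature`` (°C).  ``undersaturated``: the solution
    stays below saturation throughout.
    """

    regime: str
    crossing_temperature: Optional[float] = None

    def __post_init__(self) -> None:
        if self.regime not in ("undersaturated", "solubility-critical", "supersaturated"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if (self.regime == "solubility-critical") != (
            self.crossing_temperature is not None
        ):
            raise ValueError(
                "crossing_temperature is present exactly for the "
                "solubility-critical regime"
            )


def solubility_at(model: VantHoffModel, t_kelvin: float) -> float:
    """Solubility in wt% at an absolute temperature (kelvin)."""
    return model.solubility(t_kelvin)


def wt_to_concentration(s_wt_pct: float, density_g_per_mL: float = 1.0) -> float:
    """Convert wt% to mg/mL: ``C = S * 10 * ρ``."""
    if s_wt_pct < 0:
        raise ValueError("solubility must be >= 0 (wt%)")
    if density_g_per_mL <= 0:
        raise ValueError("density must be positive (g/mL)")
    return s_wt_pct * 10.0 * density_g_per_mL


def fit_vant_hoff(data: Sequence[tuple[float, float]]) -> VantHoffModel:
    """Least-squares van't Hoff fit to ``(T kelvin, S wt%)`` pairs.

    Exact linearization: ordinary least squares of ``ln S`` on ``1/T``
    (slope ``-ΔH_sol/R``, intercept ``ln S0``), so noiseless data are
    recovered exactly and residuals are orthogonal to ``[1, 1/T]``.
    """
    arr = np.asarray(list(data), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("data must be (T_kelvin, S_wt_pct) pairs")
    t, s = arr[:, 0], arr[:, 1]
    if np.any(t <= 0):
        raise ValueError("temperatures must be positive (kelvin)")
    if np.any(s <= 0):
        raise ValueError("solubilities must be positive for the log-space fit")
    if np.unique(t).size < 2:
        raise ValueError("need at least 2 distinct temperatures")
    design = np.column_stack([np.ones_like(t), 1.0 / t])
    coef, *_ = np.linalg.lstsq(design, np.log(s), rcond=None)
    intercept, slope = coef
    return VantHoffModel(
        s0_wt_pct=float(np.exp(intercept)),
        dh_sol_J_per_mol=float(-slope * GAS_CONSTANT),
    )


def classify_regime(
    concentration_mg_per_mL: float,
    t_range_C: tuple[float, float],
    model: VantHoffModel = PHLOROGLUCINOL_FIT,
    density_g_per_mL: float = 1.0,
) -> RegimeClassification:
    """Classify a solution's nucleation regime over a freezing range.

    ``t_range_C`` is (warm end, cold end) in °C, e.g. ``(0, -22.5)``
    from ramp start to the pure-water background.  The saturation
    concentration ``10 ρ S(T)`` decreases on cooling (ΔH_sol > 0), so a
    solution below saturation at the warm end is solubility-critical
    exactly when the curve crosses its concentration inside the range;
    the crossing temperature is located by root finding to well below
    0.01 °C.
    """
    warm, cold = t_range_C
    if warm <= cold:
        raise ValueError("t_range_C must be (warm, cold) with warm > cold")
    c = concentration_mg_per_mL

    def saturation(t_c: float) -> float:
        return wt_to_concentration(
            model.solubility(t_c + KELVIN), density_g_per_mL
        )

    if c > saturation(warm):
        return RegimeClassification(regime="supersaturated")
    if c <= saturation(cold):
        return RegimeClassification(regime="undersaturated")
    t_cross = brentq(lambda t: saturation(t) - c, cold, warm, xtol=1e-10)
    return RegimeClassification(
        regime="solubility-critical", crossing_temperature=float(t_cross)
    )
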