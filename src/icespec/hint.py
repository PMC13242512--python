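"""Classical nucleation theory for finite ice-binding patches.

Maps an ice-binding surface patch — a square of side ``L`` with an
ice-binding free energy ``Δγ_bind`` (the reduction of the ice-surface
interfacial cost relative to the liquid-surface one) — to the
heterogeneous nucleation temperature ``T_het`` at which its nucleation
rate reaches the experimental detection threshold, and inverts a target
temperature back to the required patch size.

Model
-----
The ice nucleus is a spherical cap on the patch.  The binding strength
sets the Young contact angle relative to the no-binding case,

    cos(theta) = 2 * Δγ_bind / γ(T) - 1,

so ``Δγ_bind = 0`` reproduces the homogeneous barrier (theta = 180°)
and ``Δγ_bind = γ`` perfect wetting.  While the cap footprint fits
inside the patch (mapped to an equivalent-area circular footprint of
radius ``R = L / sqrt(pi)``), the barrier is the classical
``f(theta) * 16 pi γ³ / (3 Δμ_v²)``.  Once the footprint reaches the
patch boundary the contact line pins: the nucleus must bulge past a
pinned spherical-cap saddle whose curvature radius equals the critical
radius ``r* = 2 γ / Δμ_v``, which exists whenever ``R < r*`` and raises
the barrier toward the homogeneous one as the patch shrinks.  The
free-energy barrier is the maximum over the growth path, i.e. the
larger of the unconstrained-cap and pinned saddles.

The rate is ``J(T) = A0 * D(T)/D(0 °C) * exp(-ΔG*/kB T)`` with a
diffusivity-proportional kinetic prefactor; ``T_het`` solves
``J(T_het) = J_exp`` (default 1e5 / cm³ / s, the detection condition of
a ~1 °C/min cooling ramp).

Water properties (all config-overridable): chemical potential
difference liquid-ice from the integrated heat-capacity difference,
Vogel-Fulcher-Tammann self-diffusivity, and a linear-in-T ice-liquid
surface tension anchored near 30 mJ/m² at the melting point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "WaterPropertyModel",
    "IceBindingPatch",
    "HintResult",
    "DEFAULT_WATER",
    "water_properties",
    "nucleation_rate",
    "solve_T_het",
    "invert_patch_size",
    "size_activity_curve",
    "BelowDetectableRange",
    "UnreachableTarget",
]

KB = 1.380649e-23  # J/K
T_MELT = 273.15  # K
#: molar volume of ice Ih (m^3/mol): 18.015 g/mol at 916.7 kg/m^3
V_MOLAR_ICE = 18.015e-3 / 916.7
#: default experimental rate threshold (1/cm^3/s)
J_EXP_DEFAULT = 1e5
#: default kinetic prefactor magnitude at 0 °C (1/cm^3/s)
PREFACTOR_DEFAULT = 1e37


class BelowDetectableRange(Exception):
    """The nucleation rate never reaches the threshold in the valid range."""


class UnreachableTarget(Exception):
    """The target temperature exceeds the large-patch plateau."""


@dataclass(frozen=True)
class WaterPropertyModel:
    """Parameterized thermodynamic and kinetic properties of supercooled water.

    Parameters
    ----------
    delta_mu_params
        ``(dH_melt, dcp)`` in J/mol and J/(mol K): melting enthalpy and
        the (constant) heat-capacity difference liquid minus ice, giving
        ``Δμ(T) = dH_melt (1 - T/Tm) - dcp [(Tm - T) - T ln(Tm/T)]``
        with T in kelvin.  Zero exactly at 0 °C, positive below.
    diffusivity_params
        ``(D0, B, T0)`` of the Vogel-Fulcher-Tammann law
        ``D(T) = D0 exp(-B / (T - T0))`` in m²/s, K, K.
    surface_tension_params
        ``(gamma0, slope)``: ice-liquid surface tension in J/m² as
        ``γ(T) = gamma0 + slope * T_C``, decreasing on cooling for a
        positive slope per °C.
    valid_range
        Temperatures (°C) over which the parameterization is trusted.
    """

    delta_mu_params: tuple[float, float] = (6010.0, 37.7)
    diffusivity_params: tuple[float, float, float] = (4.14e-8, 347.0, 177.0)
    surface_tension_params: tuple[float, float] = (29.5e-3, 0.09e-3)
    valid_range: tuple[float, float] = (-38.0, 0.0)

    def _check(self, t_c: float) -> None:
        lo, hi = self.valid_range
        if not lo <= t_c <= hi:
            raise ValueError(
                f"temperature {t_c} °C outside valid range [{lo}, {hi}] °C"
            )

    def delta_mu(self, t_c: float) -> float:
        """Liquid-ice chemical potential difference, J/mol (>= 0 below 0 °C)."""
        dh, dcp = self.delta_mu_params
        t = t_c + T_MELT
        return dh * (T_MELT - t) / T_MELT - dcp * (
            (T_MELT - t) - t * math.log(T_MELT / t)
        )

    def diffusivity(self, t_c: float) -> float:
        """Self-diffusion coefficient of water, m²/s."""
        d0, b, t0 = self.diffusivity_params
        return d0 * math.exp(-b / (t_c + T_MELT - t0))

    def surface_tension(self, t_c: float) -> float:
        """Ice-liquid surface tension, J/m²."""
        g0, slope = self.surface_tension_params
        return g0 + slope * t_c


DEFAULT_WATER = WaterPropertyModel()


@dataclass(frozen=True)
class IceBindingPatch:
    """A square ice-binding patch of side ``L`` (nm).

    The binding strength may be given either as an absolute interfacial
    free-energy reduction ``delta_gamma_bind`` (J/m²) or as a fraction
    ``binding_fraction`` of the temperature-dependent ice-liquid surface
    tension (a binding site whose strength tracks γ(T)); exactly one
    must be set.  ``strong()`` builds the near-maximal binder (0.95 γ)
    used as the "strong binding" reference.
    """

    side_length_nm: float
    delta_gamma_bind: float | None = None
    binding_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.side_length_nm <= 0:
            raise ValueError("side_length_nm must be positive")
        if (self.delta_gamma_bind is None) == (self.binding_fraction is None):
            raise ValueError(
                "set exactly one of delta_gamma_bind (J/m²) or binding_fraction"
            )
        if self.delta_gamma_bind is not None and self.delta_gamma_bind < 0:
            raise ValueError("delta_gamma_bind must be >= 0")
        if self.binding_fraction is not None and not (
            0.0 <= self.binding_fraction <= 1.0
        ):
            raise ValueError("binding_fraction must lie in [0, 1]")

    @classmethod
    def strong(cls, side_length_nm: float) -> "IceBindingPatch":
        return cls(side_length_nm=side_length_nm, binding_fraction=0.95)

    def cos_contact_angle(self, gamma: float) -> float:
        """``cos(theta) = 2 Δγ_bind / γ - 1``; errors if Δγ_bind > γ."""
        if self.binding_fraction is not None:
            frac = self.binding_fraction
        else:
            frac = self.delta_gamma_bind / gamma
            if frac > 1.0 + 1e-12:
                raise ValueError(
                    f"delta_gamma_bind ({self.delta_gamma_bind:.4g} J/m²) "
                    f"exceeds the ice-liquid surface tension ({gamma:.4g} J/m²)"
                )
        return 2.0 * min(frac, 1.0) - 1.0

    @property
    def footprint_radius_m(self) -> float:
        """Equivalent-area circular footprint radius, meters."""
        return self.side_length_nm * 1e-9 / math.sqrt(math.pi)


@dataclass(frozen=True)
class HintResult:
    """Heterogeneous nucleation temperature and barrier diagnostics."""

    t_het_C: float
    barrier_J: float
    critical_radius_nm: float
    limited_by_patch: bool

    def __post_init__(self) -> None:
        if self.barrier_J < 0:
            raise ValueError("barrier must be non-negative")


def water_properties(
    model: WaterPropertyModel, t_c: float
) -> tuple[float, float, float]:
    """``(Δμ, D, γ)`` at temperature ``t_c`` (°C), range-checked."""
    model._check(t_c)
    return (
        model.delta_mu(t_c),
        model.diffusivity(t_c),
        model.surface_tension(t_c),
    )


def _barrier(
    patch: IceBindingPatch, t_c: float, model: WaterPropertyModel
) -> tuple[float, bool]:
    """Free-energy barrier (J) and whether the pinned saddle governs."""
    gamma = model.surface_tension(t_c)
    dmu_v = model.delta_mu(t_c) / V_MOLAR_ICE  # J/m^3
    if dmu_v <= 0:
        return math.inf, False
    c = patch.cos_contact_angle(gamma)
    r_star = 2.0 * gamma / dmu_v
    g_hom = 16.0 * math.pi / 3.0 * gamma**3 / dmu_v**2
    f_theta = (2.0 + c) * (1.0 - c) ** 2 / 4.0
    g_uncon = g_hom * f_theta
    R = patch.footprint_radius_m
    if R >= r_star:
        return g_uncon, False
    # pinned saddle: spherical cap with base radius R and curvature r*,
    # apparent angle psi* > 90 deg, i.e. cos(psi*) = -sqrt(1 - (R/r*)^2)
    x = -math.sqrt(1.0 - (R / r_star) ** 2)
    bracket = (
        -(2.0 / 3.0) * (1.0 - x) ** 2 * (2.0 + x)
        + 2.0 * (1.0 - x)
        - c * (1.0 - x * x)
    )
    g_pin = math.pi * gamma * r_star**2 * bracket
    if g_pin > g_uncon:
        return g_pin, True
    return g_uncon, False


def nucleation_rate(
    patch: IceBindingPatch,
    t_c: float,
    model: WaterPropertyModel = DEFAULT_WATER,
    prefactor: float = PREFACTOR_DEFAULT,
) -> tuple[float, float]:
    """Nucleation rate (1/cm³/s) and barrier (J) for a patch at ``t_c``.

    ``J = A0 * D(T)/D(0 °C) * exp(-ΔG*/kB T)``.  Only the order of
    magnitude of ``A0`` matters for the predicted temperature (a 10x
    change in threshold or prefactor shifts ``T_het`` by ~1 °C).
    """
    model._check(t_c)
    barrier, _ = _barrier(patch, t_c, model)
    t_k = t_c + T_MELT
    a_t = prefactor * model.diffusivity(t_c) / model.diffusivity(0.0)
    if math.isinf(barrier):
        return 0.0, barrier
    return a_t * math.exp(-barrier / (KB * t_k)), barrier


def _log10_rate(patch, t_c, model, prefactor) -> float:
    barrier, _ = _barrier(patch, t_c, model)
    if math.isinf(barrier):
        return -math.inf
    t_k = t_c + T_MELT
    a_t = prefactor * model.diffusivity(t_c) / model.diffusivity(0.0)
    return math.log10(a_t) - barrier / (KB * t_k) / math.log(10.0)


def solve_T_het(
    patch: IceBindingPatch,
    model: WaterPropertyModel = DEFAULT_WATER,
    j_exp: float = J_EXP_DEFAULT,
    prefactor: float = PREFACTOR_DEFAULT,
) -> HintResult:
    """Temperature at which the patch's nucleation rate reaches ``j_exp``.

    Bisection on ``log10 J(T) = log10 j_exp`` to |ΔT| <= 0.01 °C.  The
    rate increases monotonically on cooling (the barrier shrinks faster
    than the kinetics slow, over the valid range), so the warmest
    crossing is the detection temperature.  Raises
    :class:`BelowDetectableRange` if the rate stays below threshold
    everywhere in the valid range.
    """
    lo, hi = model.valid_range
    hi = min(hi, -1e-6)  # Δμ vanishes at 0 °C; stay strictly below melting
    target = math.log10(j_exp)

    def g(t):
        return _log10_rate(patch, t, model, prefactor) - target

    if g(lo) < 0.0:
        raise BelowDetectableRange(
            f"nucleation rate stays below {j_exp:g} /cm³/s down to {lo} °C"
        )
    if g(hi) >= 0.0:
        t_het = hi
    else:
        a, b = lo, hi  # g(a) >= 0 > g(b); root bracketed
        while b - a > 0.005:
            m = 0.5 * (a + b)
            if g(m) >= 0.0:
                a = m
            else:
                b = m
        t_het = 0.5 * (a + b)
    barrier, pinned = _barrier(patch, t_het, model)
    gamma = model.surface_tension(t_het)
    dmu_v = model.delta_mu(t_het) / V_MOLAR_ICE
    return HintResult(
        t_het_C=t_het,
        barrier_J=barrier,
        critical_radius_nm=2.0 * gamma / dmu_v * 1e9,
        limited_by_patch=pinned,
    )


def size_activity_curve(
    l_grid_nm: np.ndarray,
    binding_fraction: float = 0.95,
    model: WaterPropertyModel = DEFAULT_WATER,
    j_exp: float = J_EXP_DEFAULT,
    prefactor: float = PREFACTOR_DEFAULT,
) -> np.ndarray:
    """``T_het`` (°C) for each patch side length on ``l_grid_nm``.

    Non-decreasing in L: small patches force the nucleus toward the
    homogeneous spherical limit, large patches saturate at the
    unbounded-surface temperature of the given binding strength.
    """
    l_grid_nm = np.asarray(l_grid_nm, dtype=float)
    out = np.empty(l_grid_nm.shape)
    for i, L in enumerate(l_grid_nm):
        patch = IceBindingPatch(side_length_nm=L, binding_fraction=binding_fraction)
        try:
            out[i] = solve_T_het(patch, model, j_exp, prefactor).t_het_C
        except BelowDetectableRange:
            out[i] = np.nan
    return out


def invert_patch_size(
    t_target_C: float,
    binding_fraction: float = 0.95,
    model: WaterPropertyModel = DEFAULT_WATER,
    j_exp: float = J_EXP_DEFAULT,
    prefactor: float = PREFACTOR_DEFAULT,
    l_max_nm: float = 100.0,
) -> float:
    """Smallest patch side length whose ``T_het`` reaches ``t_target_C``.

    Bisection on L to 0.05 nm.  Raises :class:`UnreachableTarget` when
    the target is warmer than the large-patch plateau for this binding
    strength.
    """

    def t_het(L: float) -> float:
        patch = IceBindingPatch(side_length_nm=L, binding_fraction=binding_fraction)
        try:
            return solve_T_het(patch, model, j_exp, prefactor).t_het_C
        except BelowDetectableRange:
            return -math.inf

    if t_het(l_max_nm) < t_target_C:
        raise UnreachableTarget(
            f"T_het = {t_target_C} °C is unreachable at binding fraction "
            f"{binding_fraction} (plateau {t_het(l_max_nm):.2f} °C)"
        )
    lo = 0.05  # below any physical patch; T_het(lo) ~ homogeneous
    if t_het(lo) >= t_target_C:
        return lo
    a, b = lo, l_max_nm  # t_het(a) < target <= t_het(b)
    while b - a > 0.025:
        m = 0.5 * (a + b)
        if t_het(m) >= t_target_C:
            b = m
        else:
            a = m
    return b
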