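"""Droplet-freezing assay data model and spectrum statistics.

A droplet freezing assay cools an array of equal-volume droplets at a
constant rate and records the temperature at which each droplet freezes.
From the per-droplet freezing temperatures this module computes

* the frozen fraction ``f_ice(T)`` — the fraction of droplets frozen at
  or above temperature ``T``,
* the assay efficiency summary ``T50`` (temperature at which half the
  droplets are frozen),
* the cumulative nucleation-site spectrum ``N_m(T)`` via the Vali
  inversion ``N_m = -ln(1 - f_ice) / (V * C_m)``, which assumes
  nucleation sites are Poisson-distributed across droplets,
* the smoothed differential spectrum ``n_m(T) = -dN_m/dT``, the density
  of site characteristic temperatures per unit mass, and
* paired per-droplet statistics between freeze-thaw cycles.

All temperatures are signed degrees Celsius; "colder" always means a
more negative value, and monotonicity statements are in the cooling
direction (decreasing temperature).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_interp_spline
from scipy.signal import savgol_filter
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

#: Columns required in an event table (one row per droplet per cycle).
EVENT_COLUMNS = ("droplet_id", "cycle", "freezing_temp_C", "frozen")


class T50NotReached(Exception):
    """Raised when a frozen-fraction curve never attains 0.5.

    Signals "no T50" distinctly from any numeric result; dilute assays
    in which fewer than half the droplets freeze above background have
    no meaningful T50.
    """


@dataclass(frozen=True)
class DropletAssay:
    """A droplet freezing experiment: protocol metadata plus event table.

    Parameters
    ----------
    events
        One row per droplet per cycle with columns ``droplet_id``,
        ``cycle``, ``freezing_temp_C`` and ``frozen`` (0/1).  Unfrozen
        droplets (``frozen == 0``) carry no usable temperature and are
        treated as surviving to the end of the ramp.
    droplet_volume
        Droplet volume in mL (3 µL = 0.003 mL in the reference assay).
    mass_concentration
        Solute mass concentration in mg/mL.
    cooling_rate
        Ramp rate in °C/min.
    ramp_start, ramp_end
        Warm and cold end of the cooling ramp in °C; ``ramp_start``
        must exceed ``ramp_end``.
    background_limit
        Temperature near which pure-water (background) freezing occurs
        in the instrument; informational.
    """

    events: pd.DataFrame
    droplet_volume: float = 0.003
    mass_concentration: float = 10.0
    cooling_rate: float = 1.0
    ramp_start: float = 0.0
    ramp_end: float = -30.0
    background_limit: float = -22.5

    def __post_init__(self) -> None:
        if self.droplet_volume <= 0:
            raise ValueError("droplet_volume must be positive (mL)")
        if self.mass_concentration < 0:
            raise ValueError("mass_concentration must be >= 0 (mg/mL)")
        if not self.ramp_start > self.ramp_end:
            raise ValueError(
                f"ramp_start ({self.ramp_start}) must be warmer than "
                f"ramp_end ({self.ramp_end})"
            )
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")
        ev = self.events
        frozen = ev[ev["frozen"].astype(bool)]
        t = frozen["freezing_temp_C"].to_numpy(dtype=float)
        bad = (t > self.ramp_start) | (t < self.ramp_end)
        if bad.any():
            rows = frozen.index[bad].tolist()[:5]
            raise ValueError(
                f"freezing temperatures outside ramp "
                f"[{self.ramp_end}, {self.ramp_start}] at rows {rows}"
            )
        dup = ev.duplicated(subset=["droplet_id", "cycle"])
        if dup.any():
            rows = ev.index[dup].tolist()[:5]
            raise ValueError(f"duplicate (droplet_id, cycle) pairs at rows {rows}")

    @property
    def cycles(self) -> list[int]:
        """Sorted cycle indices present in the event table."""
        return sorted(self.events["cycle"].unique().tolist())

    def cycle_events(self, cycle: int) -> pd.DataFrame:
        """Event rows for one cycle; raises on an absent/empty cycle."""
        sub = self.events[self.events["cycle"] == cycle]
        if sub.empty:
            raise ValueError(f"cycle {cycle} not present in assay")
        return sub


@dataclass(frozen=True)
class FrozenFractionCurve:
    """``f_ice`` on a strictly decreasing temperature grid."""

    temperatures: np.ndarray
    f_ice: np.ndarray
    n_droplets: int

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        f = np.asarray(self.f_ice, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "f_ice", f)
        if t.ndim != 1 or t.size < 2 or not np.all(np.diff(t) < 0):
            raise ValueError("temperature grid must be 1-D and strictly decreasing")
        if f.shape != t.shape:
            raise ValueError("f_ice and temperatures must have equal length")
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("f_ice values must lie in [0, 1]")
        if np.any(np.diff(f) < -1e-12):
            raise ValueError("f_ice must be non-decreasing as temperature decreases")


@dataclass(frozen=True)
class CumulativeSpectrum:
    """Cumulative nucleation sites per unit mass, ``N_m(T)`` in 1/mg."""

    temperatures: np.ndarray
    N_m: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        n = np.asarray(self.N_m, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "N_m", n)
        if np.any(n < 0):
            raise ValueError("N_m must be non-negative")
        if np.any(np.diff(n) < -1e-9 * max(1.0, float(n.max(initial=0.0)))):
            raise ValueError("N_m must be non-decreasing as temperature decreases")


@dataclass(frozen=True)
class SmoothingSettings:
    """Settings for the spline + Savitzky-Golay differential spectrum.

    The cumulative spectrum is interpolated with a B-spline of degree
    ``spline_degree``, differentiated analytically, and the resulting
    density is smoothed with a Savitzky-Golay filter of polynomial
    order ``polyorder`` over ``window_length`` points (first order over
    a window of 3 by default).
    """

    spline_degree: int = 3
    polyorder: int = 1
    window_length: int = 3

    def __post_init__(self) -> None:
        if self.window_length % 2 == 0:
            raise ValueError("window_length must be odd")
        if self.window_length < self.polyorder + 1:
            raise ValueError("window_length must be >= polyorder + 1")


@dataclass(frozen=True)
class DifferentialSpectrum:
    """Differential site density ``n_m(T)`` in 1/(mg °C)."""

    temperatures: np.ndarray
    n_m: np.ndarray
    smoothing_settings: SmoothingSettings = field(default_factory=SmoothingSettings)
    n_clipped: int = 0


@dataclass(frozen=True)
class CycleComparison:
    """Paired per-droplet freezing statistics across two cycles.

    ``mean_shift`` is the mean of (cycle-b minus cycle-a) freezing
    temperatures over droplets frozen in both cycles; negative means
    droplets froze colder in cycle b.  ``warm_tail_shift`` and
    ``cold_tail_shift`` restrict the mean shift to droplets in the
    warmest / coldest quartile of cycle-a temperatures, resolving
    whether efficient and inefficient nucleators evolve differently.
    """

    pairs: pd.DataFrame
    mean_shift: float
    rank_correlation: float
    warm_tail_shift: float
    cold_tail_shift: float


def default_grid(assay: DropletAssay, step: float = 0.5) -> np.ndarray:
    """Temperature grid from ramp start to ramp end in ``step`` °C steps.

    The 0.5 °C default is finer than the ±0.2 °C instrument uncertainty
    typical of IR-camera freezing detection.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    return np.arange(assay.ramp_start, assay.ramp_end - 1e-9, -step)


def compute_frozen_fraction(
    assay: DropletAssay, cycle: int, grid: np.ndarray | None = None
) -> FrozenFractionCurve:
    """Empirical frozen fraction for one cycle on a temperature grid.

    ``f_ice(T)`` counts droplets with freezing temperature at or above
    ``T`` (ties at a grid temperature count as frozen), divided by all
    droplets recorded in the cycle, frozen or not.
    """
    if grid is None:
        grid = default_grid(assay)
    grid = np.asarray(grid, dtype=float)
    if grid.max() > assay.ramp_start + 1e-9 or grid.min() < assay.ramp_end - 1e-9:
        raise ValueError(
            f"grid outside ramp [{assay.ramp_end}, {assay.ramp_start}]"
        )
    ev = assay.cycle_events(cycle)
    n = len(ev)
    temps = ev.loc[ev["frozen"].astype(bool), "freezing_temp_C"].to_numpy(float)
    f = (temps[None, :] >= grid[:, None]).sum(axis=1) / n
    return FrozenFractionCurve(temperatures=grid, f_ice=f, n_droplets=n)


def compute_T50(curve: FrozenFractionCurve) -> float:
    """Temperature at which half the droplets are frozen.

    Linear interpolation between the grid points bracketing
    ``f_ice = 0.5``.  If the curve sits exactly at 0.5 over a plateau,
    the warmest plateau temperature is returned (deterministic
    tie-break).  Raises :class:`T50NotReached` if the curve never
    attains 0.5.
    """
    t, f = curve.temperatures, curve.f_ice
    if f.max() < 0.5:
        raise T50NotReached("f_ice never reaches 0.5 on this grid")
    idx = int(np.argmax(f >= 0.5))  # first (warmest) index with f >= 0.5
    if f[idx] == 0.5 or idx == 0:
        return float(t[idx])
    f0, f1 = f[idx - 1], f[idx]
    t0, t1 = t[idx - 1], t[idx]
    return float(t0 + (0.5 - f0) * (t1 - t0) / (f1 - f0))


def vali_cumulative(
    curve: FrozenFractionCurve, volume: float, mass_concentration: float
) -> CumulativeSpectrum:
    """Invert a frozen-fraction curve into the cumulative site spectrum.

    ``N_m(T) = -ln(1 - f_ice(T)) / (V * C_m)`` with the droplet volume
    ``V`` in mL and mass concentration ``C_m`` in mg/mL, assuming
    nucleation sites are Poisson-distributed across droplets.  Grid
    points with ``f_ice = 1`` are excluded (the inversion diverges
    there) with a logged note.
    """
    if volume <= 0 or mass_concentration <= 0:
        raise ValueError("volume and mass_concentration must be positive")
    f = curve.f_ice
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("f_ice values must lie in [0, 1]")
    keep = f < 1.0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "vali_cumulative: excluded %d grid points with f_ice = 1 "
            "(N_m diverges there)",
            n_dropped,
        )
    t = curve.temperatures[keep]
    n_m = -np.log1p(-f[keep]) / (volume * mass_concentration)
    return CumulativeSpectrum(temperatures=t, N_m=n_m)


def differential_spectrum(
    cumulative: CumulativeSpectrum,
    settings: SmoothingSettings | None = None,
    grid: np.ndarray | None = None,
) -> DifferentialSpectrum:
    """Differentiate a cumulative spectrum into the site-density spectrum.

    The cumulative spectrum is spline-interpolated, differentiated with
    respect to decreasing temperature (``n_m = -dN_m/dT >= 0`` for a
    monotone ``N_m``), and smoothed with a Savitzky-Golay filter.  Any
    negative values produced by the filter are clipped to zero and
    counted; more than 10 % clipped points triggers a warning.
    """
    if settings is None:
        settings = SmoothingSettings()
    t = cumulative.temperatures
    n_min = max(settings.spline_degree + 1, 4)
    if t.size < n_min:
        raise ValueError(
            f"need at least {n_min} grid points for the differential "
            f"spectrum; got {t.size}"
        )
    if grid is None:
        grid = t
    grid = np.asarray(grid, dtype=float)
    # spline wants increasing x; temperatures decrease, so fit on -T
    spline = make_interp_spline(-t, cumulative.N_m, k=settings.spline_degree)
    n_m = spline.derivative()(-grid)  # dN_m/d(-T) = -dN_m/dT
    if grid.size >= settings.window_length:
        n_m = savgol_filter(
            n_m, window_length=settings.window_length, polyorder=settings.polyorder
        )
    negative = n_m < 0
    n_clipped = int(negative.sum())
    if n_clipped > 0.10 * n_m.size:
        warnings.warn(
            f"differential_spectrum: {n_clipped}/{n_m.size} points were "
            "negative before clipping; the cumulative spectrum may be "
            "too noisy for this smoothing window",
            stacklevel=2,
        )
    n_m = np.clip(n_m, 0.0, None)
    return DifferentialSpectrum(
        temperatures=grid, n_m=n_m, smoothing_settings=settings, n_clipped=n_clipped
    )


def compare_cycles(assay: DropletAssay, cycle_a: int, cycle_b: int) -> CycleComparison:
    """Paired freezing-temperature statistics between two cycles.

    Only droplets frozen in both cycles enter the pairing.  The rank
    correlation (Spearman) measures whether droplets retain their
    relative freezing order across cycles — the signature of a
    persistent per-droplet nucleator population.  Tail shifts restrict
    the mean cycle-to-cycle change to the warmest and coldest quartile
    of cycle-a temperatures.
    """
    ev_a = assay.cycle_events(cycle_a)
    ev_b = assay.cycle_events(cycle_b)
    a = ev_a[ev_a["frozen"].astype(bool)].set_index("droplet_id")["freezing_temp_C"]
    b = ev_b[ev_b["frozen"].astype(bool)].set_index("droplet_id")["freezing_temp_C"]
    shared = a.index.intersection(b.index)
    if len(shared) < 2:
        raise ValueError(
            f"cycles {cycle_a} and {cycle_b} share fewer than 2 frozen droplets"
        )
    pairs = pd.DataFrame(
        {
            "droplet_id": shared,
            "T_cycle_a": a.loc[shared].to_numpy(float),
            "T_cycle_b": b.loc[shared].to_numpy(float),
        }
    )
    delta = pairs["T_cycle_b"] - pairs["T_cycle_a"]
    rho = spearmanr(pairs["T_cycle_a"], pairs["T_cycle_b"]).statistic
    ta = pairs["T_cycle_a"]
    warm_cut = ta.quantile(0.75)
    cold_cut = ta.quantile(0.25)
    return CycleComparison(
        pairs=pairs,
        mean_shift=float(delta.mean()),
        rank_correlation=float(rho),
        warm_tail_shift=float(delta[ta >= warm_cut].mean()),
        cold_tail_shift=float(delta[ta <= cold_cut].mean()),
    )
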