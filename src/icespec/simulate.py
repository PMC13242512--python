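"""Synthetic droplet-freezing assays with Poisson site statistics.

Each droplet carries a Poisson-distributed number of nucleation sites,
``K ~ Poisson(lambda)`` with ``lambda = n_tot * C_m * V``, and each
site's characteristic freezing temperature is drawn from the underlying
mixture distribution.  On a cooling ramp the droplet freezes at its
warmest site, or at a pure-water background draw (normal around
-22.5 °C, truncated to the ramp) when that beats all sites or no sites
exist.  The per-droplet maxima therefore follow the analytic survival
law ``P(freeze at or above T) = 1 - exp(-lambda * F_u(T))`` away from
the background, which is exactly the forward model the deconvolution
inverts.

Population transforms emulate the processes that reshape nucleator
populations between measurements:

* **aging** — chemical degradation shifts mode locations colder and
  retains only a fraction of each subpopulation's site density;
* **freeze-thaw** (solubility-critical regime) — sites active at warm
  temperatures lose efficiency while cold-active sites gain;
* **recovery** — freeze-driven precipitation of fresh crystals restores
  a fraction of the warm subpopulation.

With ``memory=True`` (default) every droplet keeps its site set across
cycles and transforms act site-by-site, giving the paired cycle-to-
cycle correlation a real assay shows; ``memory=False`` redraws sites
independently each cycle from the transformed population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from icespec.assay import DropletAssay
from icespec.hub import GaussianComponent, UnderlyingDistribution

__all__ = [
    "SimulationConfig",
    "AgingTransform",
    "FreezeThawTransform",
    "RecoveryTransform",
    "simulate_assay",
    "apply_transform",
    "fresh_population",
]

#: expected sites per droplet beyond which the simulation refuses to run
MAX_LAMBDA = 1e7


def fresh_population(
    modes: tuple[float, ...] = (-7.8, -12.0),
    spreads: tuple[float, ...] = (1.0, 1.0),
    weights: tuple[float, ...] = (0.5, 0.5),
    n_tot: float = 10.0 / (0.003 * 10.0),
) -> UnderlyingDistribution:
    """Bimodal reference population of a fresh solubility-critical solution.

    Defaults: equal-weight modes at -7.8 and -12 °C with 1 °C spreads,
    and a total site density such that a 3 µL droplet at 10 mg/mL
    carries on average 10 sites.
    """
    comps = tuple(
        GaussianComponent(weight=w, t_mode=m, spread=s)
        for w, m, s in zip(weights, modes, spreads)
    )
    return UnderlyingDistribution(components=comps, n_tot=n_tot)


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1]; got {value}")


@dataclass(frozen=True)
class AgingTransform:
    """Shift modes colder and retain a fraction of each subpopulation.

    ``mode_shifts`` are added to the component modes (negative =
    colder); ``retained_fractions`` scale each component's absolute
    site density.  Scalars broadcast over components.
    """

    mode_shifts: tuple[float, ...] = (-1.1, -3.2)
    retained_fractions: tuple[float, ...] = (0.44, 1.0)

    def __post_init__(self) -> None:
        for f in self.retained_fractions:
            _check_fraction("retained_fraction", f)


@dataclass(frozen=True)
class FreezeThawTransform:
    """Memory effect of cycling a solubility-critical solution.

    Removes ``warm_loss_fraction`` of the warmest component's site
    density and boosts the coldest component's density by
    ``cold_boost_fraction``.
    """

    warm_loss_fraction: float = 0.3
    cold_boost_fraction: float = 0.3

    def __post_init__(self) -> None:
        _check_fraction("warm_loss_fraction", self.warm_loss_fraction)
        _check_fraction("cold_boost_fraction", self.cold_boost_fraction)


@dataclass(frozen=True)
class RecoveryTransform:
    """Freeze-driven recrystallization restoring warm-mode activity.

    Adds back ``warm_restore_fraction`` of the warmest component's
    current site density (~19 % for a single freeze-thaw of an aged
    solubility-critical solution).
    """

    warm_restore_fraction: float = 0.19

    def __post_init__(self) -> None:
        _check_fraction("warm_restore_fraction", self.warm_restore_fraction)


Transform = Union[AgingTransform, FreezeThawTransform, RecoveryTransform]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate a reproducible synthetic assay.

    Defaults emulate the reference high-throughput assay: 768 droplets
    of 3 µL at 10 mg/mL cooled at 1 °C/min from 0 to -30 °C, with
    pure-water background freezing at -22.5 °C (spread 0.4 °C) and the
    fresh bimodal population of :func:`fresh_population`.
    """

    seed: int = 0
    n_droplets: int = 768
    droplet_volume: float = 0.003
    mass_concentration: float = 10.0
    #: None simulates pure water: freezing by instrument background only
    population: Optional[UnderlyingDistribution] = field(
        default_factory=fresh_population
    )
    background_mean: float = -22.5
    background_spread: float = 0.4
    cooling_rate: float = 1.0
    ramp_start: float = 0.0
    ramp_end: float = -30.0
    n_cycles: int = 1
    transform: Optional[Transform] = None
    memory: bool = True
    bin_to: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.background_spread <= 0:
            raise ValueError("background_spread must be positive")
        if self.population is None and self.transform is not None:
            raise ValueError("transforms need a nucleator population")


def _component_densities(pop: UnderlyingDistribution) -> np.ndarray:
    return pop.weights * pop.n_tot


def _population_from_densities(
    pop: UnderlyingDistribution,
    densities: np.ndarray,
    modes: np.ndarray,
    spreads: np.ndarray,
) -> UnderlyingDistribution:
    keep = densities > 0
    if not keep.any():
        raise ValueError("transform removed every nucleation site")
    densities, modes, spreads = densities[keep], modes[keep], spreads[keep]
    n_tot = float(densities.sum())
    weights = densities / n_tot
    weights[-1] = 1.0 - weights[:-1].sum()  # exact simplex closure
    comps = tuple(
        GaussianComponent(weight=float(w), t_mode=float(m), spread=float(s))
        for w, m, s in zip(weights, modes, spreads)
    )
    return UnderlyingDistribution(components=comps, n_tot=n_tot)


def apply_transform(
    population: UnderlyingDistribution,
    transform: Transform,
    seed: int | None = None,
) -> UnderlyingDistribution:
    """Population-level action of a transform.

    Deterministic: transforms rescale component site densities and
    shift modes; weights are renormalized to sum to 1 while ``n_tot``
    tracks the absolute density change.  (``seed`` is accepted for
    interface symmetry with the site-level application inside
    :func:`simulate_assay`, where stochastic thinning uses it.)
    """
    dens = _component_densities(population)
    modes = population.modes.copy()
    spreads = population.spreads.copy()
    if isinstance(transform, AgingTransform):
        shifts = np.broadcast_to(
            np.asarray(transform.mode_shifts, dtype=float), modes.shape
        )
        retained = np.broadcast_to(
            np.asarray(transform.retained_fractions, dtype=float), dens.shape
        )
        modes = modes + shifts
        dens = dens * retained
    elif isinstance(transform, FreezeThawTransform):
        warm = int(np.argmax(modes))
        cold = int(np.argmin(modes))
        dens = dens.copy()
        dens[warm] *= 1.0 - transform.warm_loss_fraction
        dens[cold] *= 1.0 + transform.cold_boost_fraction
    elif isinstance(transform, RecoveryTransform):
        warm = int(np.argmax(modes))
        dens = dens.copy()
        dens[warm] *= 1.0 + transform.warm_restore_fraction
    else:
        raise TypeError(f"unknown transform type {type(transform).__name__}")
    return _population_from_densities(population, dens, modes, spreads)


def _draw_sites(
    rng: np.random.Generator, pop: UnderlyingDistribution, lam_total: float, n: int
) -> list[list[np.ndarray]]:
    """Per-droplet, per-component site temperature arrays."""
    sites: list[list[np.ndarray]] = [[] for _ in range(n)]
    for comp in pop.components:
        lam_c = lam_total * comp.weight
        counts = rng.poisson(lam_c, size=n)
        draws = rng.normal(comp.t_mode, comp.spread, size=int(counts.sum()))
        offsets = np.concatenate([[0], np.cumsum(counts)])
        for i in range(n):
            sites[i].append(draws[offsets[i] : offsets[i + 1]])
    return sites


def _transform_sites(
    rng: np.random.Generator,
    sites: list[list[np.ndarray]],
    pop: UnderlyingDistribution,
    new_pop: UnderlyingDistribution,
    transform: Transform,
    lam_per_density: float,
) -> list[list[np.ndarray]]:
    """Site-level action of a transform on persistent droplet site sets.

    Thinning uses Bernoulli survival per site, density gains add fresh
    Poisson-distributed sites, and mode shifts translate surviving site
    temperatures, so the marginal site distribution after the update
    matches ``apply_transform``'s population.
    """
    n = len(sites)
    old_dens = _component_densities(pop)
    modes = pop.modes
    if isinstance(transform, AgingTransform):
        shifts = np.broadcast_to(
            np.asarray(transform.mode_shifts, dtype=float), modes.shape
        )
        retained = np.broadcast_to(
            np.asarray(transform.retained_fractions, dtype=float), modes.shape
        )
        out = []
        for drop in sites:
            new_drop = []
            for arr, keep_p, shift in zip(drop, retained, shifts):
                survived = arr[rng.random(arr.size) < keep_p] + shift
                new_drop.append(survived)
            out.append(new_drop)
        return out
    if isinstance(transform, FreezeThawTransform):
        warm = int(np.argmax(modes))
        cold = int(np.argmin(modes))
        gain = lam_per_density * old_dens[cold] * transform.cold_boost_fraction
        out = []
        extra_counts = rng.poisson(gain, size=n)
        comp = pop.components[cold]
        extra = rng.normal(comp.t_mode, comp.spread, size=int(extra_counts.sum()))
        offs = np.concatenate([[0], np.cumsum(extra_counts)])
        for i, drop in enumerate(sites):
            new_drop = list(drop)
            arr = new_drop[warm]
            new_drop[warm] = arr[
                rng.random(arr.size) >= transform.warm_loss_fraction
            ]
            new_drop[cold] = np.concatenate(
                [new_drop[cold], extra[offs[i] : offs[i + 1]]]
            )
            out.append(new_drop)
        return out
    if isinstance(transform, RecoveryTransform):
        warm = int(np.argmax(modes))
        gain = lam_per_density * old_dens[warm] * transform.warm_restore_fraction
        extra_counts = rng.poisson(gain, size=n)
        comp = pop.components[warm]
        extra = rng.normal(comp.t_mode, comp.spread, size=int(extra_counts.sum()))
        offs = np.concatenate([[0], np.cumsum(extra_counts)])
        out = []
        for i, drop in enumerate(sites):
            new_drop = list(drop)
            new_drop[warm] = np.concatenate(
                [new_drop[warm], extra[offs[i] : offs[i + 1]]]
            )
            out.append(new_drop)
        return out
    raise TypeError(f"unknown transform type {type(transform).__name__}")


def simulate_assay(config: SimulationConfig) -> DropletAssay:
    """Generate a droplet assay event table from a simulation config.

    Fully reproducible from ``config.seed``.  Every droplet freezes
    within the ramp (the truncated background draw guarantees a
    freezing event), so all rows carry ``frozen = 1``.
    """
    pop = config.population
    lam = 0.0 if pop is None else (
        pop.n_tot * config.mass_concentration * config.droplet_volume
    )
    if lam > MAX_LAMBDA:
        raise ValueError(
            f"expected sites per droplet lambda = {lam:.3g} exceeds "
            f"{MAX_LAMBDA:g}; unphysical site load"
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_droplets
    lam_per_density = config.mass_concentration * config.droplet_volume

    sites = (
        [[] for _ in range(n)] if pop is None else _draw_sites(rng, pop, lam, n)
    )

    a = (config.ramp_end - config.background_mean) / config.background_spread
    b = (config.ramp_start - config.background_mean) / config.background_spread

    rows = []
    for cycle in range(1, config.n_cycles + 1):
        if cycle > 1:
            if config.transform is not None:
                new_pop = apply_transform(pop, config.transform)
                if config.memory:
                    sites = _transform_sites(
                        rng, sites, pop, new_pop, config.transform, lam_per_density
                    )
                else:
                    lam_new = new_pop.n_tot * lam_per_density
                    sites = _draw_sites(rng, new_pop, lam_new, n)
                pop = new_pop
            elif not config.memory:
                sites = _draw_sites(rng, pop, lam, n)
        background = truncnorm.rvs(
            a,
            b,
            loc=config.background_mean,
            scale=config.background_spread,
            size=n,
            random_state=rng,
        )
        for i in range(n):
            warmest = max((arr.max() for arr in sites[i] if arr.size), default=-np.inf)
            t_freeze = max(warmest, background[i])
            t_freeze = min(max(t_freeze, config.ramp_end), config.ramp_start)
            if config.bin_to is not None:
                t_freeze = round(t_freeze / config.bin_to) * config.bin_to
                t_freeze = min(max(t_freeze, config.ramp_end), config.ramp_start)
            rows.append((i, cycle, t_freeze, 1))

    events = pd.DataFrame(
        rows, columns=["droplet_id", "cycle", "freezing_temp_C", "frozen"]
    )
    return DropletAssay(
        events=events,
        droplet_volume=config.droplet_volume,
        mass_concentration=config.mass_concentration,
        cooling_rate=config.cooling_rate,
        ramp_start=config.ramp_start,
        ramp_end=config.ramp_end,
        background_limit=config.background_mean,
    )
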