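import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import ndtr

from icespec import (
    FitSettings,
    FrozenFractionCurve,
    GaussianComponent,
    HUBFitResult,
    SimulationConfig,
    UnderlyingDistribution,
    fit_underlying,
    forward_f_ice,
    mode_summary,
    select_best,
    simulate_assay,
    compute_frozen_fraction,
)
from icespec.hub import deconvolve
from icespec.simulate import fresh_population

V, CM = 0.003, 10.0
GRID = np.arange(0.0, -30.001, -0.5)


def single(mode=-12.0, spread=1.0, n_tot=10.0 / (V * CM)):
    return UnderlyingDistribution(
        components=(GaussianComponent(weight=1.0, t_mode=mode, spread=spread),),
        n_tot=n_tot,
    )


class TestForwardModel:
    def test_zero_far_above_modes(self):
        f = forward_f_ice(single(), V, CM, np.array([-0.5, -1.0])).f_ice
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_saturating_value_far_below_modes(self):
        # V * C_m * n_tot = 1 and full survival: f = 1 - 1/e
        dist = single(n_tot=1.0 / (V * CM))
        f = forward_f_ice(dist, V, CM, np.array([-28.0, -29.0])).f_ice
        np.testing.assert_allclose(f, 1.0 - np.exp(-1.0), atol=1e-6)

    def test_half_survival_at_the_mode(self):
        lam = V * CM * single().n_tot
        f = forward_f_ice(single(), V, CM, np.array([-11.0, -12.0])).f_ice
        assert f[1] == pytest.approx(1.0 - np.exp(-0.5 * lam), abs=1e-9)

    def test_monotone_for_any_parameters(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            p = rng.integers(1, 4)
            w = rng.dirichlet(np.ones(p))
            comps = tuple(
                GaussianComponent(
                    weight=float(wi),
                    t_mode=float(rng.uniform(-38, 0)),
                    spread=float(rng.uniform(0.05, 5)),
                )
                for wi in w
            )
            dist = UnderlyingDistribution(comps, n_tot=float(10 ** rng.uniform(-2, 4)))
            f = forward_f_ice(dist, V, CM, GRID).f_ice
            assert np.all(np.diff(f) >= -1e-12)

    def test_mixture_density_normalized(self, bimodal_population):
        total, _ = quad(lambda t: bimodal_population.pdf(t)[0], -60.0, 20.0)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestFitUnderlying:
    def test_noiseless_self_consistency(self, bimodal_population):
        curve = forward_f_ice(bimodal_population, V, CM, GRID)
        result = fit_underlying(
            curve, 2, V, CM, FitSettings(n_restarts=3, maxiter=400), seed=1
        )
        assert result.mse < 1e-6

    def test_single_component_recovery_across_seeds(self):
        """Mode of a unimodal population recovered within 0.3 degC.

        Three expected sites per droplet keep the N_m plateau
        observable (f_ice saturates at ~0.95), which identifies n_tot;
        the background region is excluded from the objective.
        """
        pop = single(mode=-12.0, spread=1.0, n_tot=3.0 / (V * CM))
        settings = FitSettings(n_restarts=2, maxiter=200, t_min=-20.0)
        hits = 0
        for seed in range(10):
            assay = simulate_assay(
                SimulationConfig(seed=300 + seed, population=pop)
            )
            curve = compute_frozen_fraction(assay, 1)
            result = fit_underlying(curve, 1, V, CM, settings, seed=seed)
            if abs(result.distribution.modes[0] + 12.0) <= 0.3:
                hits += 1
        assert hits >= 9

    def test_two_separated_components_recovered(self):
        pop = fresh_population(
            modes=(-6.0, -16.0), spreads=(1.0, 1.0), n_tot=3.0 / (V * CM)
        )
        assay = simulate_assay(SimulationConfig(seed=77, population=pop))
        curve = compute_frozen_fraction(assay, 1)
        result = fit_underlying(
            curve, 2, V, CM,
            FitSettings(n_restarts=3, maxiter=300, t_min=-20.0),
            seed=5,
        )
        modes = result.distribution.modes
        weights = result.distribution.weights
        assert modes[0] == pytest.approx(-6.0, abs=0.3)
        assert modes[1] == pytest.approx(-16.0, abs=0.3)
        assert weights[0] == pytest.approx(0.5, abs=0.1)

    def test_brute_force_oracle_equivalence(self):
        """On a coarse grid the optimizer matches an exhaustive search."""
        n_tot = 10.0 / (V * CM)
        grid = np.array([-4.0, -7.0, -10.0, -13.0, -16.0])
        truth = single(mode=-9.3, spread=1.4, n_tot=n_tot)
        noisy = np.clip(
            forward_f_ice(truth, V, CM, grid).f_ice
            + np.array([0.02, -0.03, 0.01, -0.02, 0.015]),
            0.0,
            1.0,
        )
        curve = FrozenFractionCurve(grid, np.sort(noisy), n_droplets=0)
        settings = FitSettings(n_restarts=3, maxiter=400, fixed_n_tot=n_tot)
        fitted = fit_underlying(curve, 1, V, CM, settings, seed=2)

        modes = np.linspace(-20, -2, 361)
        spreads = np.linspace(0.05, 5, 200)
        mm, ss = np.meshgrid(modes, spreads)
        surv = ndtr((mm[None] - grid[:, None, None]) / ss[None])
        fm = 1.0 - np.exp(-V * CM * n_tot * surv)
        brute = ((fm - curve.f_ice[:, None, None]) ** 2).mean(axis=0).min()
        assert fitted.mse <= brute * 1.1

    def test_degenerate_and_invalid_inputs(self):
        flat = FrozenFractionCurve(GRID, np.zeros_like(GRID), n_droplets=8)
        with pytest.raises(ValueError, match="degenerate"):
            fit_underlying(flat, 1, V, CM)
        curve = forward_f_ice(single(), V, CM, GRID)
        with pytest.raises(ValueError, match="p"):
            fit_underlying(curve, 0, V, CM)


class TestSelection:
    def _result(self, mse, p=2, seed=0):
        return HUBFitResult(
            distribution=single(), mse=mse, p=p, seed=seed, n_restarts=1
        )

    def test_lowest_mse_wins(self):
        results = [self._result(1e-3), self._result(5e-4, p=3)]
        assert select_best(results).mse == 5e-4

    def test_parsimony_tie_break(self):
        results = [self._result(1e-4, p=3), self._result(1e-4, p=2)]
        assert select_best(results).p == 2

    def test_single_element_and_empty(self):
        only = self._result(1.0)
        assert select_best([only]) is only
        with pytest.raises(ValueError):
            select_best([])

    def test_deconvolve_prefers_true_component_count(self, bimodal_population):
        curve = forward_f_ice(bimodal_population, V, CM, GRID)
        best = deconvolve(
            curve,
            V,
            CM,
            p_values=(1, 2),
            settings=FitSettings(n_restarts=2, maxiter=300),
            seed=4,
        )
        assert best.p == 2


class TestModeSummary:
    def test_single_component_weight_one(self):
        table = mode_summary(single())
        assert table["weight"].tolist() == [1.0]

    def test_equal_components_split_density(self, bimodal_population):
        table = mode_summary(bimodal_population)
        n_tot = bimodal_population.n_tot
        np.testing.assert_allclose(table["site_density_per_mg"], n_tot / 2)
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        # sorted warmest first
        assert table["t_mode_C"].is_monotonic_decreasing


class TestInvariants:
    def test_weights_must_sum_to_one(self):
        comps = (
            GaussianComponent(weight=0.6, t_mode=-8.0, spread=1.0),
            GaussianComponent(weight=0.6, t_mode=-12.0, spread=1.0),
        )
        with pytest.raises(ValueError, match="sum to 1"):
            UnderlyingDistribution(components=comps, n_tot=100.0)

    def test_mode_window_enforced(self):
        with pytest.raises(ValueError, match="window"):
            GaussianComponent(weight=1.0, t_mode=-45.0, spread=1.0)
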