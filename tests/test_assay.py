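import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from icespec import (
    CumulativeSpectrum,
    DropletAssay,
    FrozenFractionCurve,
    SimulationConfig,
    T50NotReached,
    compare_cycles,
    compute_T50,
    compute_frozen_fraction,
    default_grid,
    differential_spectrum,
    forward_f_ice,
    simulate_assay,
    vali_cumulative,
)
from icespec.simulate import FreezeThawTransform, fresh_population

from conftest import make_assay


class TestFrozenFraction:
    def test_direct_count(self):
        assay = make_assay([-5.0, -10.0, -15.0, -20.0])
        curve = compute_frozen_fraction(assay, 1, grid=np.array([-2.0, -12.0]))
        assert curve.f_ice[1] == 0.5

    def test_zero_at_warm_start(self):
        assay = make_assay([-5.0, -10.0])
        curve = compute_frozen_fraction(assay, 1)
        assert curve.f_ice[0] == 0.0

    def test_tie_counts_as_frozen(self):
        assay = make_assay([-5.0, -10.0])
        curve = compute_frozen_fraction(assay, 1, grid=np.array([-4.0, -5.0, -6.0]))
        assert list(curve.f_ice) == [0.0, 0.5, 0.5]

    def test_unfrozen_droplets_dilute_the_fraction(self):
        events = pd.DataFrame(
            {
                "droplet_id": [0, 1, 2, 3],
                "cycle": 1,
                "freezing_temp_C": [-5.0, -10.0, np.nan, np.nan],
                "frozen": [1, 1, 0, 0],
            }
        )
        assay = DropletAssay(events=events)
        curve = compute_frozen_fraction(assay, 1, grid=np.array([-1.0, -20.0]))
        assert curve.f_ice[-1] == 0.5

    def test_order_and_grid_refinement_invariance(self):
        temps = [-4.5, -8.0, -11.25, -17.0, -21.0]
        coarse = np.arange(0.0, -30.0, -1.0)
        fine = np.arange(0.0, -30.0, -0.25)
        a = compute_frozen_fraction(make_assay(temps), 1, grid=coarse)
        b = compute_frozen_fraction(make_assay(temps[::-1]), 1, grid=fine)
        shared = np.isin(fine, coarse)
        np.testing.assert_array_equal(a.f_ice, b.f_ice[shared])

    def test_empty_cycle_and_bad_grid_error(self):
        assay = make_assay([-5.0])
        with pytest.raises(ValueError, match="cycle"):
            compute_frozen_fraction(assay, 2)
        with pytest.raises(ValueError, match="grid"):
            compute_frozen_fraction(assay, 1, grid=np.array([5.0, -1.0]))

    def test_simulated_curve_within_binomial_envelope(self, fresh_assay):
        """Empirical f_ice tracks the forward model of its own generator."""
        config, assay = fresh_assay
        curve = compute_frozen_fraction(assay, 1)
        model = forward_f_ice(
            config.population,
            config.droplet_volume,
            config.mass_concentration,
            curve.temperatures,
        )
        n = curve.n_droplets
        half_width = 2.576 * np.sqrt(model.f_ice * (1 - model.f_ice) / n) + 1.0 / n
        outside = np.abs(curve.f_ice - model.f_ice) > half_width
        assert outside.sum() <= 2


class TestT50:
    @pytest.mark.parametrize(
        "temps, f, expected",
        [
            ([-8.0, -9.0, -11.0, -12.0], [0.0, 0.0, 1.0, 1.0], -10.0),
            ([-10.0, -11.0, -12.0, -13.0, -14.0], [0.0, 0.25, 0.5, 0.75, 1.0], -12.0),
            ([-7.0, -8.0, -10.0, -11.0], [0.2, 0.4, 0.6, 1.0], -9.0),
        ],
    )
    def test_interpolation(self, temps, f, expected):
        curve = FrozenFractionCurve(np.array(temps), np.array(f), n_droplets=10)
        assert compute_T50(curve) == pytest.approx(expected)

    def test_plateau_reports_warmest_point(self):
        curve = FrozenFractionCurve(
            np.array([-6.0, -7.0, -8.0, -9.0]),
            np.array([0.0, 0.5, 0.5, 1.0]),
            n_droplets=10,
        )
        assert compute_T50(curve) == -7.0

    def test_not_reached_is_distinct(self):
        curve = FrozenFractionCurve(
            np.array([-6.0, -7.0]), np.array([0.0, 0.4]), n_droplets=10
        )
        with pytest.raises(T50NotReached):
            compute_T50(curve)


class TestVali:
    def test_zero_fraction_gives_zero_sites(self):
        curve = FrozenFractionCurve(
            np.array([-1.0, -2.0]), np.array([0.0, 0.0]), n_droplets=4
        )
        spec = vali_cumulative(curve, 0.003, 10.0)
        np.testing.assert_array_equal(spec.N_m, [0.0, 0.0])

    def test_half_fraction_value(self):
        # -ln(0.5) / (0.003 mL * 10 mg/mL) = 23.10 per mg
        curve = FrozenFractionCurve(
            np.array([-1.0, -2.0]), np.array([0.0, 0.5]), n_droplets=4
        )
        spec = vali_cumulative(curve, 0.003, 10.0)
        assert spec.N_m[1] == pytest.approx(23.1049, abs=1e-3)

    def test_round_trip_to_machine_precision(self, fresh_curve):
        spec = vali_cumulative(fresh_curve, 0.003, 10.0)
        f_back = 1.0 - np.exp(-0.003 * 10.0 * spec.N_m)
        keep = fresh_curve.f_ice < 1.0
        np.testing.assert_allclose(f_back, fresh_curve.f_ice[keep], atol=1e-12)

    def test_saturated_points_excluded(self):
        curve = FrozenFractionCurve(
            np.array([-1.0, -2.0, -3.0]), np.array([0.0, 0.5, 1.0]), n_droplets=4
        )
        spec = vali_cumulative(curve, 0.003, 10.0)
        assert spec.temperatures.size == 2
        assert np.isfinite(spec.N_m).all()

    def test_invalid_inputs_error(self, fresh_curve):
        with pytest.raises(ValueError):
            vali_cumulative(fresh_curve, -1.0, 10.0)


class TestDifferentialSpectrum:
    def test_constant_cumulative_gives_zero_density(self):
        spec = CumulativeSpectrum(np.arange(0.0, -5.0, -0.5), np.full(10, 7.0))
        diff = differential_spectrum(spec)
        np.testing.assert_allclose(diff.n_m, 0.0, atol=1e-9)

    def test_linear_cumulative_gives_constant_slope(self):
        t = np.arange(0.0, -5.0, -0.5)
        spec = CumulativeSpectrum(t, -3.0 * t)  # N_m = 3 per degree of cooling
        diff = differential_spectrum(spec)
        np.testing.assert_allclose(diff.n_m, 3.0, atol=1e-9)

    def test_single_gaussian_peak_location(self):
        """Peak of n_m falls within 0.2 degC of the generating mode."""
        t = np.arange(0.0, -24.0, -0.25)
        n_tot, mode, s = 100.0, -12.0, 1.5
        spec = CumulativeSpectrum(t, n_tot * norm.sf(t, mode, s))
        diff = differential_spectrum(spec)
        peak = diff.temperatures[np.argmax(diff.n_m)]
        assert abs(peak - mode) <= 0.2
        # analytic density: n_m(T) = n_tot * pdf(T), away from the far tails
        expected = n_tot * norm.pdf(t, mode, s)
        core = expected > 0.1 * expected.max()
        np.testing.assert_allclose(diff.n_m[core], expected[core], rtol=0.05)

    def test_integral_recovers_cumulative(self):
        """Integrating n_m over the grid reproduces N_m at the cold end."""
        from icespec.simulate import fresh_population

        grid = np.arange(0.0, -20.001, -0.25)
        smooth = forward_f_ice(fresh_population(), 0.003, 10.0, grid)
        spec = vali_cumulative(smooth, 0.003, 10.0)
        diff = differential_spectrum(spec)
        integral = np.trapezoid(diff.n_m, -diff.temperatures)
        assert integral == pytest.approx(spec.N_m[-1] - spec.N_m[0], rel=0.02)

    def test_too_few_points_error(self):
        spec = CumulativeSpectrum(np.array([-1.0, -2.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="at least"):
            differential_spectrum(spec)


class TestCycleComparison:
    def test_identical_cycles(self):
        temps = [-5.0, -8.0, -11.0, -14.0]
        events = pd.concat(
            [
                make_assay(temps, cycle=1).events,
                make_assay(temps, cycle=2).events,
            ]
        ).reset_index(drop=True)
        cmp = compare_cycles(DropletAssay(events=events), 1, 2)
        assert cmp.mean_shift == 0.0
        assert cmp.rank_correlation == pytest.approx(1.0)

    def test_permuted_cycle_decorrelates(self):
        rng = np.random.default_rng(42)
        temps = rng.uniform(-20, -5, size=768)
        ev1 = make_assay(temps, cycle=1).events
        ev2 = make_assay(rng.permutation(temps), cycle=2).events
        cmp = compare_cycles(
            DropletAssay(events=pd.concat([ev1, ev2]).reset_index(drop=True)), 1, 2
        )
        assert abs(cmp.rank_correlation) < 0.2

    def test_memory_effect_sign_pattern(self):
        """Warm-active nucleators lose efficiency, cold-active ones gain."""
        pop = fresh_population(
            modes=(-7.0, -13.0), spreads=(0.8, 0.8), n_tot=2.0 / 0.03
        )
        config = SimulationConfig(
            seed=5,
            population=pop,
            n_cycles=2,
            transform=FreezeThawTransform(
                warm_loss_fraction=0.6, cold_boost_fraction=1.0
            ),
            memory=True,
        )
        cmp = compare_cycles(simulate_assay(config), 1, 2)
        assert cmp.warm_tail_shift < 0
        assert cmp.cold_tail_shift > 0

    def test_disjoint_droplets_error(self):
        ev1 = make_assay([-5.0, -6.0], cycle=1).events
        ev2 = make_assay([-5.0, -6.0], cycle=2).events
        ev2["droplet_id"] += 10
        assay = DropletAssay(events=pd.concat([ev1, ev2]).reset_index(drop=True))
        with pytest.raises(ValueError, match="share"):
            compare_cycles(assay, 1, 2)


class TestAssayValidation:
    def test_temperature_outside_ramp(self):
        with pytest.raises(ValueError, match="outside ramp"):
            make_assay([-35.0])

    def test_duplicate_droplet_cycle(self):
        events = pd.DataFrame(
            {
                "droplet_id": [0, 0],
                "cycle": [1, 1],
                "freezing_temp_C": [-5.0, -6.0],
                "frozen": [1, 1],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            DropletAssay(events=events)

    def test_inverted_ramp(self):
        with pytest.raises(ValueError, match="ramp_start"):
            make_assay([-5.0], ramp_start=-30.0, ramp_end=0.0)

    def test_default_grid_step(self):
        assay = make_assay([-5.0])
        grid = default_grid(assay)
        assert grid[0] == 0.0
        assert np.allclose(np.diff(grid), -0.5)
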