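"""Spin-bath Monte Carlo, rate law, and the height -> T1 calibration."""

import numpy as np
import pytest

from nvtension import (
    CalibrationError,
    GdBath,
    MonteCarloConfig,
    NVCenter,
    SensorPhysics,
    calibrate_constants,
    calibration_curve,
    expected_pixel_curve,
    expected_pixel_t1,
    fit_stretched_exponential,
    mc_mean_bath_rate,
    mean_bath_rate_analytic,
    pixel_decay_curve,
    pixel_t1,
    sample_gd_bath,
    sample_nv_ensemble,
    single_nv_rate,
)
from nvtension.spin_bath import NV_ORIENTATIONS


class TestSampling:
    def test_nv_count_is_poisson_with_mean_area_times_density(self):
        # 600x600 nm^2 at 1000/um^2 -> mean 360.
        rng = np.random.default_rng(5)
        counts = [
            len(sample_nv_ensemble((600, 600), 1000.0, seed=rng)) for _ in range(300)
        ]
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - 360) < 4 * se + 1e-9

    def test_zero_density_gives_empty_ensemble_and_bath(self):
        assert sample_nv_ensemble((600, 600), 0.0, seed=1) == []
        assert sample_gd_bath((600, 600), 0.0, 2.0, seed=1).n_ions == 0

    def test_seed_determinism(self):
        a = sample_nv_ensemble((600, 600), 1000.0, seed=42)
        b = sample_nv_ensemble((600, 600), 1000.0, seed=42)
        assert len(a) == len(b)
        assert all(
            (p.x, p.y, p.depth) == (q.x, q.y, q.depth)
            and np.array_equal(p.orientation, q.orientation)
            for p, q in zip(a, b)
        )
        ba = sample_gd_bath((700, 700), 9000.0, 2.0, seed=7)
        bb = sample_gd_bath((700, 700), 9000.0, 2.0, seed=7)
        assert np.array_equal(ba.positions, bb.positions)

    def test_orientations_drawn_from_the_four_crystal_axes(self):
        nvs = sample_nv_ensemble((2000, 2000), 1000.0, seed=3)
        counts = np.zeros(4)
        for nv in nvs:
            matches = np.where((NV_ORIENTATIONS == nv.orientation).all(axis=1))[0]
            assert matches.size == 1
            counts[matches[0]] += 1
        # Roughly uniform across the four axes.
        freqs = counts / counts.sum()
        assert freqs.min() > 0.15 and freqs.max() < 0.35

    def test_positions_inside_region(self):
        nvs = sample_nv_ensemble((600, 400), 1000.0, seed=9)
        assert all(0 <= nv.x <= 600 and 0 <= nv.y <= 400 for nv in nvs)

    def test_mean_ions_inside_cutoff_disc(self):
        # pi * 0.05^2 * 9000 ~ 70.7 ions within one NV's 50 nm cutoff.
        rng = np.random.default_rng(11)
        hits = []
        for _ in range(200):
            bath = sample_gd_bath((200, 200), 9000.0, 2.0, seed=rng)
            d2 = ((bath.positions - 100.0) ** 2).sum(axis=1)
            hits.append(int((d2 <= 50.0**2).sum()))
        assert np.mean(hits) == pytest.approx(np.pi * 0.05**2 * 9000 * 1e6 * 1e-6, rel=0.05)

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            sample_nv_ensemble((600, 600), -1.0)
        with pytest.raises(ValueError):
            sample_gd_bath((600, 600), 9000.0, -0.5)
        with pytest.raises(ValueError):
            NVCenter(0, 0, -5.0, NV_ORIENTATIONS[0])
        with pytest.raises(ValueError):
            GdBath(-1.0, np.zeros((0, 2)), 9000.0)


class TestRateLaw:
    def test_single_ion_directly_above(self):
        # r = 10 nm (depth 5 + height 5), C = 1e6 -> bath term exactly 1/us.
        phys = SensorPhysics(coupling=1e6, gamma_int=1e-3)
        nv = NVCenter(0.0, 0.0, 5.0, NV_ORIENTATIONS[0])
        bath = GdBath(5.0, np.array([[0.0, 0.0]]), density=1.0)
        assert single_nv_rate(nv, bath, phys) == pytest.approx(1e-3 + 1.0, rel=1e-12)

    def test_inverse_sixth_power_distance_scaling(self):
        phys = SensorPhysics(coupling=1e6, gamma_int=1e-3)
        nv = NVCenter(0.0, 0.0, 5.0, NV_ORIENTATIONS[0])
        near = GdBath(5.0, np.array([[0.0, 0.0]]), 1.0)
        far = GdBath(15.0, np.array([[0.0, 0.0]]), 1.0)  # r: 10 -> 20 nm
        r_near = single_nv_rate(nv, near, phys) - 1e-3
        r_far = single_nv_rate(nv, far, phys) - 1e-3
        assert r_near / r_far == pytest.approx(64.0, rel=1e-9)

    def test_empty_bath_returns_intrinsic_rate(self):
        phys = SensorPhysics(coupling=1e6, gamma_int=2e-3)
        nv = NVCenter(0, 0, 5.0, NV_ORIENTATIONS[1])
        bath = GdBath(2.0, np.zeros((0, 2)), 0.0)
        assert single_nv_rate(nv, bath, phys) == 2e-3

    def test_ions_beyond_lateral_cutoff_do_not_contribute(self):
        phys = SensorPhysics(coupling=1e6, gamma_int=1e-3)
        nv = NVCenter(0, 0, 5.0, NV_ORIENTATIONS[0])
        bath = GdBath(2.0, np.array([[60.0, 0.0]]), 1.0, cutoff_radius=50.0)
        assert single_nv_rate(nv, bath, phys) == 1e-3

    def test_secular_weight_bounded_and_reduces_to_isotropic_on_average(self):
        iso = SensorPhysics(1e6, 1e-3, "isotropic")
        sec = SensorPhysics(1e6, 1e-3, "secular")
        nv = NVCenter(0, 0, 5.0, NV_ORIENTATIONS[0])
        rng = np.random.default_rng(2)
        pos = rng.uniform(-50, 50, (2000, 2))
        bath = GdBath(2.0, pos, 9000.0)
        r_iso = single_nv_rate(nv, bath, iso) - 1e-3
        r_sec = single_nv_rate(nv, bath, sec) - 1e-3
        # w = (5 - 3cos^2)/4 lies in [1/2, 5/4]
        assert 0.5 * r_iso <= r_sec <= 1.25 * r_iso

    def test_monte_carlo_mean_matches_planar_integral(self, physics):
        """Brute-force bath average vs the closed-form r^-6 disc integral."""
        for h in (0.5, 2.0, 6.0):
            mc, se = mc_mean_bath_rate(h, physics, n_replicates=3000, seed=123)
            exact = mean_bath_rate_analytic(h, physics)
            assert abs(mc - exact) < max(4 * se, 0.01 * exact)

    def test_disc_sampler_consistent_with_rectangular_bath_sampler(self, physics):
        # The fast oracle sampler (per-disc Poisson) must agree with the
        # literal pipeline: rectangular bath + lateral cutoff per NV.
        h = 2.0
        rng = np.random.default_rng(77)
        nv = NVCenter(100.0, 100.0, 5.0, NV_ORIENTATIONS[0])
        vals = []
        for _ in range(1500):
            bath = sample_gd_bath((200, 200), 9000.0, h, seed=rng)
            vals.append(single_nv_rate(nv, bath, physics) - physics.gamma_int)
        slow_mean = np.mean(vals)
        slow_se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        fast_mean, fast_se = mc_mean_bath_rate(h, physics, 1500, nv_per_replicate=1, seed=88)
        assert abs(slow_mean - fast_mean) < 4 * np.hypot(slow_se, fast_se)


class TestPixelCurve:
    def test_single_nv_gives_pure_exponential(self, physics, mc_config):
        nv = [NVCenter(300, 300, 5.0, NV_ORIENTATIONS[0])]
        bath = sample_gd_bath((700, 700), 9000.0, 2.0, seed=4, origin=(-50, -50))
        curve = pixel_decay_curve(nv, bath, physics, mc_config.tau_grid)
        fit = fit_stretched_exponential(curve)
        assert fit.converged
        assert fit.b == pytest.approx(1.0, abs=1e-3)

    def test_equal_rates_stay_exponential_regardless_of_count(self, physics, mc_config):
        # All NVs at the same position see the same bath -> identical rates.
        nvs = [NVCenter(300, 300, 5.0, NV_ORIENTATIONS[k % 4]) for k in range(10)]
        bath = sample_gd_bath((700, 700), 9000.0, 2.0, seed=4, origin=(-50, -50))
        curve = pixel_decay_curve(nvs, bath, physics, mc_config.tau_grid)
        fit = fit_stretched_exponential(curve)
        assert fit.b == pytest.approx(1.0, abs=1e-3)

    def test_heterogeneous_rates_stretch_the_summed_curve(self, mc_config):
        # Two-rate mixture: the summed curve fits with b < 1 (brute-force
        # construction, no bath sampling involved).
        tau = mc_config.tau_grid
        mix = 0.1 * 0.5 * (np.exp(-tau / 100.0) + np.exp(-tau / 900.0)) + 1.0
        from nvtension import DecayCurve

        fit = fit_stretched_exponential(DecayCurve(tau, mix))
        assert fit.converged
        assert fit.b < 0.95

    def test_monotone_non_increasing(self, physics, mc_config):
        nvs = sample_nv_ensemble((600, 600), 1000.0, seed=6)
        bath = sample_gd_bath((700, 700), 9000.0, 1.0, seed=7, origin=(-50, -50))
        curve = pixel_decay_curve(nvs, bath, physics, mc_config.tau_grid)
        assert np.all(np.diff(curve.intensity) <= 1e-12)

    def test_empty_pixel_is_an_error(self, physics, mc_config):
        bath = sample_gd_bath((700, 700), 9000.0, 1.0, seed=7)
        with pytest.raises(ValueError):
            pixel_decay_curve([], bath, physics, mc_config.tau_grid)


class TestPixelT1:
    def test_t1_increases_with_height(self, physics):
        lo = pixel_t1(0.3, physics, seed=21)
        hi = pixel_t1(6.0, physics, seed=22)
        assert hi.t1 > lo.t1

    def test_bath_removed_recovers_intrinsic_t1(self, physics):
        cfg = MonteCarloConfig(gd_density_per_um2=1e-9)
        res = pixel_t1(3.0, physics, cfg, seed=5)
        assert res.fit.converged
        assert res.t1 == pytest.approx(1.0 / physics.gamma_int, rel=1e-3)
        assert res.b == pytest.approx(1.0, abs=1e-3)

    def test_pixel_mean_matches_expected_curve_fit(self, physics):
        """Repetition oracle: the MC pixel T1 converges on the deterministic
        fit of the exact bath-averaged curve."""
        h = 2.0
        rng = np.random.default_rng(31)
        vals = [pixel_t1(h, physics, seed=rng).t1 for _ in range(60)]
        mean = np.mean(vals)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(mean - expected_pixel_t1(h, physics)) < max(4 * se, 0.01 * mean)


class TestCalibration:
    def test_anchors_reproduced_exactly_by_construction(self, physics):
        assert expected_pixel_t1(0.3, physics) == pytest.approx(391.0, rel=1e-6)
        assert expected_pixel_t1(6.0, physics) == pytest.approx(795.0, rel=1e-6)

    def test_intrinsic_t1_exceeds_the_upper_anchor(self, physics):
        assert 1.0 / physics.gamma_int > 795.0

    def test_round_trip_constant_recovery(self, mc_config):
        # Synthesize anchors from known constants, calibrate against them,
        # and recover the constants.
        true = SensorPhysics(coupling=80.0, gamma_int=1.2e-3)
        anchors = [
            (h, expected_pixel_t1(h, true, mc_config)) for h in (0.3, 6.0)
        ]
        fitted = calibrate_constants(anchors[0], anchors[1], mc_config)
        assert fitted.coupling == pytest.approx(true.coupling, rel=1e-4)
        assert fitted.gamma_int == pytest.approx(true.gamma_int, rel=1e-4)

    def test_inconsistent_anchors_raise(self, mc_config):
        with pytest.raises(CalibrationError):
            calibrate_constants((0.3, 795.0), (6.0, 391.0), mc_config)

    def test_analytic_curve_monotone_and_serializable(self, calibration):
        assert np.all(np.diff(calibration.t1_us_mean) > 0)
        assert calibration.t1_us_mean[0] == pytest.approx(391.0, rel=1e-6)
        assert calibration.t1_us_mean[-1] == pytest.approx(795.0, rel=1e-6)

    def test_single_point_grid_gives_single_row(self, physics):
        table = calibration_curve([2.0], physics)
        assert table.h_nm.size == 1

    def test_monte_carlo_curve_agrees_with_analytic_within_error(self, physics):
        grid = np.array([0.3, 2.0, 6.0])
        table = calibration_curve(grid, physics, replicates=12, seed=13,
                                  method="monte_carlo")
        ana = calibration_curve(grid, physics, method="analytic")
        se = table.t1_us_sd / np.sqrt(table.replicates)
        assert np.all(np.abs(table.t1_us_mean - ana.t1_us_mean) < 4 * se + 0.01 * ana.t1_us_mean)

    def test_monte_carlo_curve_deterministic_under_seed(self, physics):
        grid = np.array([1.0, 4.0])
        t1 = calibration_curve(grid, physics, replicates=4, seed=99, method="monte_carlo")
        t2 = calibration_curve(grid, physics, replicates=4, seed=99, method="monte_carlo")
        assert np.array_equal(t1.t1_us_mean, t2.t1_us_mean)
        assert np.array_equal(t1.t1_us_sd, t2.t1_us_sd)

    def test_expected_curve_is_smooth_and_decaying(self, physics, mc_config):
        curve = expected_pixel_curve(1.0, physics, mc_config)
        assert np.all(np.diff(curve.intensity) < 0)
        assert curve.intensity[0] <= mc_config.contrast_a + mc_config.contrast_c
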