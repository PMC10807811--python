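"""Stretched-exponential fitting and widefield-stack contrast extraction."""

import numpy as np
import pytest

from nvtension import (
    DecayCurve,
    WidefieldStack,
    contrast_trace,
    fit_stretched_exponential,
    region_delta_t1,
    render_widefield_stack,
    stretched_exp,
    t1_map,
)

TAU = np.geomspace(1.0, 3000.0, 24)


def make_curve(a=0.1, t1=400.0, b=1.0, c=1.0, tau=TAU, noise=0.0, rng=None):
    inten = stretched_exp(tau, a, t1, b, c)
    if noise:
        inten = inten + rng.normal(0, noise, tau.size)
    return DecayCurve(tau, inten)


class TestFit:
    @pytest.mark.parametrize("t1", [50.0, 400.0, 800.0])
    @pytest.mark.parametrize("b", [0.6, 1.0])
    def test_noiseless_recovery(self, t1, b):
        fit = fit_stretched_exponential(make_curve(t1=t1, b=b))
        assert fit.converged
        assert fit.a == pytest.approx(0.1, rel=1e-4)
        assert fit.t1 == pytest.approx(t1, rel=1e-4)
        assert fit.b == pytest.approx(b, rel=1e-4)
        assert fit.c == pytest.approx(1.0, rel=1e-4)

    def test_fixed_b_reduces_to_plain_exponential_fit(self):
        fit = fit_stretched_exponential(make_curve(b=1.0), fix_b=1.0)
        assert fit.b == 1.0
        assert fit.t1 == pytest.approx(400.0, rel=1e-6)

    def test_fixed_baseline_is_respected(self):
        fit = fit_stretched_exponential(make_curve(c=1.0), fix_c=1.0)
        assert fit.c == 1.0
        assert fit.t1 == pytest.approx(400.0, rel=1e-6)

    def test_constant_offset_moves_only_the_baseline(self):
        base = fit_stretched_exponential(make_curve())
        shifted = fit_stretched_exponential(
            DecayCurve(TAU, make_curve().intensity + 0.25)
        )
        assert shifted.c - base.c == pytest.approx(0.25, abs=1e-6)
        assert shifted.t1 == pytest.approx(base.t1, rel=1e-6)
        assert shifted.a == pytest.approx(base.a, rel=1e-6)

    def test_degenerate_constant_trace_flagged_not_raised(self):
        fit = fit_stretched_exponential(DecayCurve(TAU, np.full(TAU.size, 1.05)))
        assert not fit.converged

    def test_too_few_points_is_an_input_error(self):
        with pytest.raises(ValueError):
            fit_stretched_exponential(make_curve(tau=np.geomspace(1, 3000, 4)))

    def test_narrow_tau_span_is_an_input_error(self):
        with pytest.raises(ValueError):
            fit_stretched_exponential(make_curve(tau=np.linspace(100, 500, 12)))

    def test_nan_points_are_dropped(self):
        curve = make_curve()
        inten = curve.intensity.copy()
        inten[3] = np.nan
        fit = fit_stretched_exponential(DecayCurve(TAU, inten))
        assert fit.converged
        assert fit.n_points == TAU.size - 1
        assert fit.t1 == pytest.approx(400.0, rel=1e-6)

    def test_recovery_grid_under_mild_noise(self, rng):
        # Shot-noise-scale perturbations should not destabilize the fit.
        for t1 in (100.0, 600.0):
            fit = fit_stretched_exponential(
                make_curve(t1=t1, noise=1e-3, rng=rng), fix_b=1.0
            )
            assert fit.converged
            assert fit.t1 == pytest.approx(t1, rel=0.1)


def uniform_stack(t1=500.0, shape=(6, 6), noise=False, seed=0, budget=1e5):
    field = np.full(shape, t1)
    return render_widefield_stack(field, TAU, photons_per_pixel=budget,
                                  seed=seed, shot_noise=noise)


class TestContrastTrace:
    def test_identical_channels_divide_to_unity(self):
        frames = np.ones((TAU.size, 4, 4)) * 7.0
        stack = WidefieldStack(TAU, frames, frames.copy())
        trace = contrast_trace(stack)
        assert np.allclose(trace.intensity, 1.0)

    def test_single_pixel_bin_equals_elementwise_division(self):
        stack = uniform_stack(noise=True, seed=3)
        trace = contrast_trace(stack, (slice(2, 3), slice(1, 2)))
        direct = stack.off[:, 2, 1] / stack.on[:, 2, 1]
        assert np.allclose(trace.intensity, direct)

    def test_zero_denominator_flags_point_instead_of_crashing(self):
        stack = uniform_stack()
        stack.on[5] = 0.0
        trace = contrast_trace(stack)
        assert np.isnan(trace.intensity[5])
        assert trace.valid.sum() == TAU.size - 1

    def test_division_symmetry_swapping_channels_inverts_the_trace(self):
        stack = uniform_stack(noise=True, seed=4)
        fwd = contrast_trace(stack)
        swapped = WidefieldStack(stack.tau, stack.off, stack.on,
                                 stack.pixel_size_nm)
        rev = contrast_trace(swapped)
        assert np.allclose(fwd.intensity * rev.intensity, 1.0)

    def test_trace_matches_forward_model_within_shot_noise(self):
        stack = uniform_stack(t1=400.0, shape=(32, 32), noise=True, seed=5)
        trace = contrast_trace(stack)  # full-frame bin: noise ~ budget*npix
        model = stretched_exp(TAU, 0.1, 400.0, 1.0, 1.0)
        assert np.allclose(trace.intensity, model, atol=5e-4)


class TestT1Map:
    def test_uniform_field_recovers_with_small_scatter(self):
        stack = uniform_stack(t1=500.0, shape=(8, 8), noise=True, seed=6)
        tmap = t1_map(stack, fix_b=1.0, fix_c=1.0)
        assert tmap.converged.all()
        assert abs(np.mean(tmap.t1) - 500.0) < 25.0
        assert np.std(tmap.t1) < 0.2 * np.mean(tmap.t1)

    def test_binning_preserves_t1_on_noiseless_homogeneous_input(self):
        stack = uniform_stack(t1=450.0, shape=(8, 8), noise=False)
        t_fine = t1_map(stack, binning=1)
        t_coarse = t1_map(stack, binning=2)
        assert t_coarse.shape == (4, 4)
        assert np.allclose(t_fine.t1, 450.0, rtol=1e-4)
        assert np.allclose(t_coarse.t1, 450.0, rtol=1e-4)
        assert t_coarse.pixel_size_nm == 2 * t_fine.pixel_size_nm

    def test_shot_noise_scaling_with_photon_budget(self):
        # Quadrupling the budget should halve the per-pixel T1 scatter.
        sds = []
        for budget in (2.5e4, 1e5):
            stack = uniform_stack(t1=500.0, shape=(14, 14), noise=True,
                                  seed=8, budget=budget)
            tmap = t1_map(stack, fix_b=1.0, fix_c=1.0)
            sds.append(np.std(tmap.t1[tmap.converged]))
        ratio = sds[0] / sds[1]
        assert 1.5 < ratio < 2.7  # ideal 2, generous MC band


class TestRegionDeltaT1:
    def _map(self, values):
        values = np.asarray(values, dtype=float)
        ones = np.ones_like(values)
        return_map = None
        from nvtension import T1Map

        return T1Map(t1=values, b=ones, a=ones * 0.1, c=ones,
                     residual_norm=ones * 0.0,
                     converged=np.isfinite(values))

    def test_reference_region_has_zero_delta(self):
        tmap = self._map(np.full((5, 5), 410.0))
        stats = region_delta_t1(tmap, np.ones((5, 5), bool))
        assert stats["mean"] == 0.0
        assert stats["n"] == 25

    def test_pooled_mean_is_weighted_combination_of_disjoint_masks(self):
        vals = np.arange(16, dtype=float).reshape(4, 4) * 10 + 400
        tmap = self._map(vals)
        m1 = np.zeros((4, 4), bool); m1[:2] = True
        m2 = ~m1
        s1 = region_delta_t1(tmap, m1)
        s2 = region_delta_t1(tmap, m2)
        pooled = region_delta_t1(tmap, m1 | m2)
        combined = (s1["mean"] * s1["n"] + s2["mean"] * s2["n"]) / (s1["n"] + s2["n"])
        assert pooled["mean"] == pytest.approx(combined)

    def test_unconverged_pixels_are_excluded_and_empty_mask_raises(self):
        vals = np.full((3, 3), 500.0)
        vals[0, 0] = np.nan  # unconverged
        tmap = self._map(vals)
        stats = region_delta_t1(tmap, np.ones((3, 3), bool))
        assert stats["n"] == 8
        with pytest.raises(ValueError):
            region_delta_t1(tmap, np.zeros((3, 3), bool))
        only_bad = np.zeros((3, 3), bool); only_bad[0, 0] = True
        with pytest.raises(ValueError):
            region_delta_t1(tmap, only_bad)
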