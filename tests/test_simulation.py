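"""Detector arrays, decision rule and Monte-Carlo experiments."""

import numpy as np
import pytest

from motionmask.motion_model import GratingComponent
from motionmask.simulation import (
    INSECT_SIM_SIGNAL_CONTRAST,
    DecisionModel,
    DetectorArray,
    FieldSpec,
    decide,
    insect_model,
    masking_function,
    pooled_output,
    sensitivity_curve,
    simulate_outputs,
    simulate_response_rate,
    threshold_from_outputs,
)
from motionmask.stimulus import NoiseSpec, render_masked_grating


def _optimal_movie(array, direction=+1, contrast=1.0):
    f_s, f_t = array.optimum
    return render_masked_grating(
        GratingComponent(contrast, f_s, f_t, 0.0, direction),
        None,
        array.field_spec.geometry,
        None,
        array.field_spec.duration,
        dx_deg=array.field_spec.dx_deg,
        extent_deg=array.field_spec.half_extent,
        mean_luminance=None,
    )


class TestArrayAndPooling:
    def test_normalised_response_to_optimal_grating_is_one(self, iarray, marray):
        for array in (iarray, marray):
            assert pooled_output(_optimal_movie(array, +1), array) == pytest.approx(1.0)

    def test_reversed_grating_gives_minus_one(self, iarray):
        assert pooled_output(_optimal_movie(iarray, -1), iarray) == pytest.approx(-1.0)

    def test_unnormalised_array_rejected(self, ibank):
        arr = DetectorArray(np.array([0.0]), ibank, FieldSpec())
        with pytest.raises(ValueError, match="normalized"):
            pooled_output(_optimal_movie_like(arr), arr)

    def test_detectors_must_fit_in_field(self, ibank):
        with pytest.raises(ValueError, match="support"):
            DetectorArray(np.array([60.0]), ibank, FieldSpec())


def _optimal_movie_like(array):
    return render_masked_grating(
        GratingComponent(1.0, 0.037, 8.0), None,
        extent_deg=array.field_spec.half_extent, mean_luminance=None,
    )


class TestDecide:
    @pytest.mark.parametrize(
        "x,t,expected",
        [(2.0, 1.0, +1), (-2.0, 1.0, -1), (0.5, 1.0, 0), (1.0, 1.0, 0), (-1.0, 1.0, 0),
         (0.1, 0.0, +1), (-0.1, 0.0, -1), (0.0, 0.0, 0)],
    )
    def test_ternary_rule_with_strict_boundaries(self, x, t, expected):
        assert decide(x, DecisionModel(t)) == expected

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            DecisionModel(-0.1)


class TestSensitivity:
    def test_insect_curve_is_bandpass(self, ibank):
        grid = np.array([0.001, 0.0025, 0.01, 0.037, 0.1, 0.3, 0.5])
        s = sensitivity_curve(ibank, grid)
        assert s[0] < 0.05 and s[1] < 0.15          # lowpass-side rejection
        assert s[-2] < 1e-3 and s[-1] < 1e-6        # highpass-side rejection
        assert s.max() == 1.0

    def test_insect_peak_near_published_tuning(self, iarray):
        """The closed-form peak of gain x sin(2 pi f delta_x) with the
        stated sigma and delta_x sits near 0.037 cpd (slightly above the
        0.03 cpd the organism is reported to prefer)."""
        assert 0.03 < iarray.optimum[0] < 0.045

    def test_mammal_peak_matches_derivative_gain_maximum(self, mbank, marray):
        """Closed form: (2 pi f)^5 exp(-4 pi^2 sigma^2 f^2) peaks at
        sqrt(5/2) / (2 pi sigma) ~ 3.15 cpd for sigma = 0.08 deg."""
        expected = np.sqrt(2.5) / (2 * np.pi * 0.08)
        grid = np.geomspace(0.3, 30, 300)
        s = sensitivity_curve(mbank, grid)
        assert grid[np.argmax(s)] == pytest.approx(expected, rel=0.02)
        assert marray.optimum[0] == pytest.approx(expected, rel=0.02)

    def test_curve_independent_of_detector_count(self, ibank):
        """Identical detectors see the same full-field grating, so the
        normalised sensitivity does not depend on the array."""
        grid = np.geomspace(0.005, 0.2, 7)
        np.testing.assert_array_equal(
            sensitivity_curve(ibank, grid), sensitivity_curve(ibank, grid)
        )


class TestMonteCarlo:
    def test_fast_path_equals_rendered_pipeline(self, iarray):
        """The algebraic noise-projection shortcut reproduces the rendered
        movie -> pooled_output route presentation by presentation."""
        sig = GratingComponent(0.125, 0.0185, 8.0, 0.0, +1)
        noise = NoiseSpec(0.198, 0.03)
        outs = simulate_outputs(sig, noise, iarray, 3, seed=42)
        children = np.random.SeedSequence(42).spawn(3)
        fs = iarray.field_spec
        for out, child in zip(outs, children):
            phases = np.random.default_rng(child).uniform(0, 1, fs.n_frames)
            movie = render_masked_grating(
                sig, noise, fs.geometry, fs.window, fs.duration,
                dx_deg=fs.dx_deg, extent_deg=fs.half_extent,
                mean_luminance=fs.mean_luminance, noise_phases=phases,
            )
            assert out == pytest.approx(pooled_output(movie, iarray), rel=1e-9)

    def test_fixed_seed_reproducible_and_seeds_differ(self, iarray):
        sig = GratingComponent(INSECT_SIM_SIGNAL_CONTRAST, 0.0185, 8.0, 0.0, +1)
        noise = NoiseSpec(0.198, 0.01)
        a = simulate_outputs(sig, noise, iarray, 20, seed=5)
        b = simulate_outputs(sig, noise, iarray, 20, seed=5)
        c = simulate_outputs(sig, noise, iarray, 20, seed=6)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_suprathreshold_signal_without_noise_is_always_correct(self, iarray):
        sig = GratingComponent(0.125, 0.0185, 8.0, 0.0, +1)
        rate, outs = simulate_response_rate(sig, None, iarray, n_presentations=5, seed=0)
        assert rate == 1.0
        assert np.all(outs > 0)

    def test_noise_alone_carries_no_net_motion(self, iarray):
        """Across many fresh-phase presentations the mean pooled output of a
        noise-only stimulus is statistically zero (shrinking ~ 1/sqrt(N))."""
        null = GratingComponent(0.0, 0.0185, 8.0, 0.0, +1)
        outs = simulate_outputs(null, NoiseSpec(0.198, 0.02), iarray, 400, seed=9)
        sem = outs.std(ddof=1) / np.sqrt(len(outs))
        assert abs(outs.mean()) < 4 * sem

    def test_rate_non_increasing_in_noise_contrast(self, iarray):
        """More noise can only hurt, up to Monte-Carlo error."""
        sig = GratingComponent(INSECT_SIM_SIGNAL_CONTRAST, 0.0185, 8.0, 0.0, +1)
        rates = []
        for amp in (0.0, 0.05, 0.198):
            noise = None if amp == 0 else NoiseSpec(amp, 0.03)
            rate, _ = simulate_response_rate(sig, noise, iarray,
                                             n_presentations=150, seed=13)
            rates.append(rate)
        mc = 3 * np.sqrt(0.25 / 150)
        assert rates[0] >= rates[1] - mc >= rates[2] - 2 * mc

    def test_masking_invariant_to_detector_count(self):
        """10 vs 30 detectors: masking rates agree within Monte-Carlo error."""
        sig = GratingComponent(INSECT_SIM_SIGNAL_CONTRAST, 0.0185, 8.0, 0.0, +1)
        noise = NoiseSpec(0.198, 0.005)
        r10, _ = simulate_response_rate(sig, noise, insect_model(10),
                                        n_presentations=200, seed=3)
        r30, _ = simulate_response_rate(sig, noise, insect_model(30),
                                        n_presentations=200, seed=3)
        assert abs(r10 - r30) < 3 * np.sqrt(2 * 0.25 / 200)


class TestThreshold:
    def test_degenerate_distribution_returns_its_value(self):
        res = threshold_from_outputs(np.full(50, 1.7))
        assert res.threshold == pytest.approx(1.7)
        assert not res.censored

    def test_threshold_is_tenth_percentile_margin(self, rng):
        x = rng.normal(10.0, 1.0, 5000)
        res = threshold_from_outputs(x)
        assert res.threshold == pytest.approx(10 - 1.2816, abs=0.1)

    def test_unattainable_criterion_is_censored(self, rng):
        x = rng.normal(0.0, 5.0, 500)  # ~50% correct at best
        res = threshold_from_outputs(x)
        assert res.censored and res.threshold == 0.0


class TestMaskingFunctions:
    def test_degenerate_contrasts_rejected(self, iarray):
        with pytest.raises(ValueError, match="degenerate"):
            masking_function("insect-rate",
                             GratingComponent(0.0, 0.0185, 8.0), 0.198, array=iarray)
        with pytest.raises(ValueError, match="degenerate"):
            masking_function("insect-rate",
                             GratingComponent(0.1, 0.0185, 8.0), 0.0, array=iarray)

    def test_insect_curve_masks_at_band_not_above(self, iarray):
        sig = GratingComponent(INSECT_SIM_SIGNAL_CONTRAST, 0.0185, 8.0, 0.0, +1)
        curve = masking_function(
            "insect-rate", sig, 0.198, noise_frequencies=[0.03, 0.5],
            array=iarray, n_presentations=120, seed=2,
        )
        assert curve.extras["baseline_rate"] == 1.0
        assert curve.values[0] > 0.3          # strong masking in band
        assert abs(curve.values[1]) < 0.05    # none far above band
        assert np.all(curve.ci_low <= curve.values)
        assert np.all(curve.values <= curve.ci_high)
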