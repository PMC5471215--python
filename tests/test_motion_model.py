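"""Opponent-energy circuits against their closed-form predictions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motionmask.motion_model import (
    GratingComponent,
    OutOfRetinaError,
    SeparableResponses,
    analytic_compound_mean,
    analytic_interaction,
    analytic_single_grating,
    em_opponent,
    energy_spectrum,
    rd_opponent,
    separable_responses,
)
from motionmask.stimulus import render_masked_grating

DT = 1.0 / 85.0


class TestSeparableResponses:
    def test_zero_contrast_gives_zero_responses(self, ibank):
        c = GratingComponent(0.0, 0.03, 8.0)
        r = separable_responses([c], ibank)
        for series in (r.a, r.a_prime, r.b, r.b_prime):
            assert np.all(series == 0)

    def test_single_grating_amplitude_and_frequency(self, ibank):
        """The A channel is a sinusoid at the grating's temporal frequency
        with amplitude C * G_S1 * G_T1 (steady state)."""
        from motionmask.filters import spatial_transfer, temporal_transfer_sampled

        c = GratingComponent(0.5, 0.03, 8.0, 0.2)
        r = separable_responses([c], ibank, duration=1.0, warmup="periodic")
        expected = 0.5 * abs(spatial_transfer(ibank.sf1, 0.03)) * abs(
            temporal_transfer_sampled(ibank.tf1, 8.0, DT)
        )
        amp = (r.a.max() - r.a.min()) / 2
        assert amp == pytest.approx(expected, rel=2e-3)
        # 8 full cycles in 1 s: the dominant FFT bin sits at 8 Hz
        spec = np.abs(np.fft.rfft(r.a))
        assert np.argmax(spec[1:]) + 1 == 8

    def test_superposition_of_components(self, ibank):
        c1 = GratingComponent(0.1, 0.02, 8.0, 0.3, +1)
        c2 = GratingComponent(0.2, 0.05, 5.0, 1.0, -1)
        r12 = separable_responses([c1, c2], ibank)
        r1 = separable_responses([c1], ibank)
        r2 = separable_responses([c2], ibank)
        np.testing.assert_allclose(r12.a, r1.a + r2.a, atol=1e-12)
        np.testing.assert_allclose(r12.b_prime, r1.b_prime + r2.b_prime, atol=1e-12)

    def test_detector_outside_movie_raises(self, ibank):
        movie = render_masked_grating(
            GratingComponent(0.1, 0.03, 8.0), None, extent_deg=20.0
        )
        with pytest.raises(OutOfRetinaError):
            separable_responses(movie, ibank, position=15.0)

    def test_mismatched_series_rejected(self):
        with pytest.raises(ValueError):
            SeparableResponses(np.zeros(5), np.zeros(5), np.zeros(4), np.zeros(5), DT)


class TestCircuits:
    def test_em_constant_example(self):
        ones, zeros = np.ones(10), np.zeros(10)
        out = em_opponent(SeparableResponses(ones, zeros, zeros, ones, DT))
        assert np.all(out.series == 4.0)
        assert out.mean == 4.0

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_em_equals_four_times_rd_pointwise(self, seed):
        """The two circuits are algebraically identical up to a factor 4 for
        any shared separable responses."""
        rng = np.random.default_rng(seed)
        resp = SeparableResponses(*(rng.normal(size=64) for _ in range(4)), dt=DT)
        em = em_opponent(resp).series
        rd = rd_opponent(resp).series
        assert np.max(np.abs(em - 4 * rd)) <= 1e-10 * np.max(np.abs(rd))

    def test_direction_swap_negates_mean(self, ibank):
        c = GratingComponent(0.3, 0.03, 8.0, 0.0, +1)
        c_rev = GratingComponent(0.3, 0.03, 8.0, 0.0, -1)
        m1 = rd_opponent(separable_responses([c], ibank, warmup="periodic")).mean
        m2 = rd_opponent(separable_responses([c_rev], ibank, warmup="periodic")).mean
        assert m2 == pytest.approx(-m1, rel=1e-9)
        assert m1 != 0

    def test_counterphase_grating_averages_to_zero(self, ibank):
        """Two equal opposite-drifting components (counterphase modulation)
        drive the filters but not the opponent stage."""
        comps = [
            GratingComponent(0.25, 0.03, 8.0, 0.0, +1),
            GratingComponent(0.25, 0.03, 8.0, 0.0, -1),
        ]
        resp = separable_responses(comps, ibank, warmup="periodic")
        solo = abs(rd_opponent(separable_responses(comps[:1], ibank, warmup="periodic")).mean)
        assert abs(rd_opponent(resp).mean) < 1e-6 * solo
        assert np.max(np.abs(resp.a)) > 1e-3  # the filters do respond

    def test_fullfield_flicker_averages_to_zero(self, ibank):
        """Spatially uniform luminance modulation: photoreceptors respond,
        opponency cancels."""
        c = GratingComponent(0.4, 0.0, 8.0, 0.1)
        resp = separable_responses([c], ibank, warmup="periodic")
        assert np.max(np.abs(resp.a)) > 1e-4
        assert abs(rd_opponent(resp).mean) < 1e-12 * np.max(np.abs(resp.a)) ** 2


class TestClosedForms:
    def test_single_grating_vanishes_at_zero_spatial_frequency(self, ibank):
        assert analytic_single_grating(GratingComponent(1.0, 0.0, 8.0), ibank) == 0.0

    def test_quadratic_contrast_dependence(self, ibank):
        m1 = analytic_single_grating(GratingComponent(0.1, 0.03, 8.0), ibank)
        m2 = analytic_single_grating(GratingComponent(0.2, 0.03, 8.0), ibank)
        assert m2 == pytest.approx(4 * m1, rel=1e-12)

    def test_single_grating_matches_rendered_simulation(self, ibank):
        """Closed form vs steady-state numerics on a rendered movie."""
        c = GratingComponent(0.3, 0.03, 8.0, 0.0, +1)
        movie = render_masked_grating(
            c, None, window=None, extent_deg=25.0, mean_luminance=None
        )
        num = rd_opponent(separable_responses(movie, ibank, 0.0, warmup="periodic")).mean
        assert num == pytest.approx(analytic_single_grating(c, ibank, dt=DT), rel=0.02)

    def test_interaction_zero_across_temporal_frequencies(self, ibank):
        cj = GratingComponent(0.2, 0.02, 8.0)
        ck = GratingComponent(0.2, 0.05, 6.0)
        assert analytic_interaction(cj, ck, ibank) == 0.0

    def test_invisible_component_interacts_with_visible_one(self, ibank):
        """A very low spatial frequency component gives almost no solo
        response (phase difference ~ 0) yet a large cross term with a
        visible signal -- masking by invisible noise."""
        visible = GratingComponent(0.125, 0.0185, 8.0, 0.3, +1)
        invisible = GratingComponent(0.198, 0.0005, 8.0, 1.2, +1)
        solo = abs(analytic_single_grating(invisible, ibank))
        cross = abs(
            analytic_interaction(visible, invisible, ibank)
            + analytic_interaction(invisible, visible, ibank)
        )
        assert cross > 10 * solo
        assert cross > 0.1 * abs(analytic_single_grating(visible, ibank))

    def test_compound_decomposition_matches_numerics(self, ibank, mbank):
        """Mean output to a 3-component stimulus equals solo terms plus all
        shared-temporal-frequency cross terms."""
        for bank, comps in [
            (
                ibank,
                [
                    GratingComponent(0.125, 0.0185, 8.0, 0.4, +1),
                    GratingComponent(0.198, 0.0025, 8.0, 1.9, +1),
                    GratingComponent(0.08, 0.05, 8.0, 2.4, -1),
                ],
            ),
            (
                mbank,
                [
                    GratingComponent(1.0, 3.0, 8.0, 0.4, +1),
                    GratingComponent(2.0, 1.0, 8.0, 1.9, +1),
                    GratingComponent(0.8, 5.0, 8.0, 2.4, -1),
                ],
            ),
        ]:
            num = rd_opponent(separable_responses(comps, bank, warmup="periodic")).mean
            assert num == pytest.approx(analytic_compound_mean(comps, bank, dt=DT), rel=1e-4)


class TestEnergySpectrum:
    def test_insect_directional_energies_overlap_at_dc_but_cancel(self, ibank):
        maps = energy_spectrum(ibank, np.array([0.0]), np.array([4.0, 8.0]))
        assert np.all(maps["rightward"] > 1e-6)
        np.testing.assert_allclose(maps["rightward"], maps["leftward"], rtol=1e-12)
        np.testing.assert_allclose(maps["opponent"], 0.0, atol=1e-15)

    def test_opponent_map_antisymmetric_in_spatial_frequency(self, ibank, mbank):
        f_s = np.array([-0.08, -0.03, 0.03, 0.08])
        f_t = np.array([2.0, 8.0, 15.0])
        for bank in (ibank, mbank):
            opp = energy_spectrum(bank, f_s, f_t)["opponent"]
            np.testing.assert_allclose(opp, -opp[::-1, :], rtol=1e-9)

    def test_mammal_opponent_support_matches_directional_support(self, mbank):
        """For bandpass front ends there are no frequencies with strong
        directional energy but no opponent response (0.25 contours agree)."""
        f_s = np.geomspace(0.3, 30, 40)
        f_t = np.geomspace(0.5, 30, 30)
        maps = energy_spectrum(mbank, f_s, f_t)
        right = maps["rightward"] / maps["rightward"].max()
        opp = np.abs(maps["opponent"]) / np.abs(maps["opponent"]).max()
        strong_filter = right > 0.25
        assert np.all(opp[strong_filter] > 0.1)

    def test_insect_has_strong_filter_response_without_opponent_response(self, ibank):
        """The dissociation: lowpass filters respond at low spatial
        frequency but the opponent output there is a tiny fraction."""
        f_s = np.array([0.001])
        f_t = np.array([8.0])
        maps = energy_spectrum(ibank, f_s, f_t)
        peak = energy_spectrum(ibank, np.array([0.037]), f_t)
        assert maps["rightward"][0, 0] > 0.5 * peak["rightward"][0, 0]
        assert abs(maps["opponent"][0, 0]) < 0.05 * abs(peak["opponent"][0, 0])
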