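"""Contour algebra: geometric means, depth scaling, inversion, triangles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from formantcomp.contours import (
    TRIANGLE_PEAK,
    FormantTrack,
    TriangleSpec,
    block_smooth,
    check_min_separation,
    estimate_cycles,
    flatten_amplitude,
    geometric_mean,
    invert_about_gmean,
    scale_depth,
    triangle_contour,
    triangle_wave,
)
from formantcomp.exceptions import InvalidTrackError


def track(freqs, amps=None):
    freqs = np.asarray(freqs, dtype=float)
    return FormantTrack(freqs=freqs, amps=np.ones_like(freqs) if amps is None else np.asarray(amps, float))


class TestTrackInvariants:
    def test_empty_track_rejected(self):
        with pytest.raises(InvalidTrackError):
            FormantTrack(freqs=np.array([]), amps=np.array([]))

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(InvalidTrackError):
            track([500.0, 0.0])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(InvalidTrackError):
            FormantTrack(freqs=np.array([500.0]), amps=np.array([1.0, 1.0]))

    def test_duration(self):
        assert track([500.0] * 250).duration == pytest.approx(0.25)


class TestGeometricMean:
    @pytest.mark.parametrize(
        "freqs, expected",
        [
            ([500.0] * 7, 500.0),
            ([400.0, 900.0], 600.0),
            ([250.0, 1000.0, 250.0, 1000.0], 500.0),
        ],
    )
    def test_known_values(self, freqs, expected):
        assert geometric_mean(track(freqs)) == pytest.approx(expected)

    def test_unweighted_by_amplitude(self):
        a = track([400.0, 900.0], amps=[1.0, 1.0])
        b = track([400.0, 900.0], amps=[0.01, 1.0])
        assert geometric_mean(a) == geometric_mean(b)


class TestScaleDepth:
    def test_zero_collapses_to_gmean(self, random_track):
        g = geometric_mean(random_track)
        out = scale_depth(random_track, 0.0)
        assert np.allclose(out.freqs, g)

    def test_unity_is_identity(self, random_track):
        out = scale_depth(random_track, 1.0)
        assert np.allclose(out.freqs, random_track.freqs)

    def test_half_depth_closed_form(self):
        out = scale_depth(track([200.0, 800.0]), 0.5)
        assert out.freqs == pytest.approx([282.843, 565.685], abs=1e-3)

    def test_amplitudes_untouched(self, random_track):
        out = scale_depth(random_track, 0.3)
        assert np.array_equal(out.amps, random_track.amps)

    @pytest.mark.parametrize("x", [-0.1, 1.1])
    def test_out_of_range_factor(self, x, random_track):
        with pytest.raises(ValueError):
            scale_depth(random_track, x)

    @pytest.mark.parametrize("x", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_gmean_preserved(self, x, random_track):
        g = geometric_mean(random_track)
        g2 = geometric_mean(scale_depth(random_track, x))
        assert abs(g2 - g) / g < 1e-9

    def test_log_deviation_linearity(self, random_track):
        x = 0.37
        g = geometric_mean(random_track)
        out = scale_depth(random_track, x)
        assert np.allclose(
            np.log(out.freqs / g), x * np.log(random_track.freqs / g), atol=1e-12
        )


class TestInversion:
    def test_fixed_point_at_gmean(self):
        t = track([600.0, 600.0])
        assert np.allclose(invert_about_gmean(t).freqs, 600.0)

    def test_reflection(self):
        out = invert_about_gmean(track([300.0, 1200.0]))
        assert out.freqs == pytest.approx([1200.0, 300.0])

    def test_involution_and_gmean(self, random_track):
        twice = invert_about_gmean(invert_about_gmean(random_track))
        assert np.allclose(twice.freqs, random_track.freqs, rtol=1e-12)
        g = geometric_mean(random_track)
        g_inv = geometric_mean(invert_about_gmean(random_track))
        assert abs(g_inv - g) / g < 1e-9


class TestBlockSmooth:
    def test_constant_contour(self):
        out = block_smooth(np.full(120, 7.0), 40)
        assert np.allclose(out, 7.0) and len(out) == 3

    def test_ramp_means(self):
        assert np.allclose(block_smooth(np.arange(1, 81.0), 40), [20.5, 60.5])

    def test_partial_trailing_block(self):
        out = block_smooth(np.arange(1, 51.0), 40)
        assert np.allclose(out, [20.5, (41 + 50) / 2.0])

    def test_invalid_block(self):
        with pytest.raises(ValueError):
            block_smooth(np.ones(10), 0)


class TestEstimateCycles:
    def test_no_crossing_is_half_cycle(self):
        est = estimate_cycles(np.full(10, 600.0), g=500.0, duration=1.0)
        assert est.half_cycles == 1
        assert est.cycles == 0.5
        assert est.period_T == pytest.approx(2.0)

    def test_two_crossings(self):
        est = estimate_cycles([510.0, 490.0, 510.0], g=500.0, duration=1.0)
        assert est.half_cycles == 3
        assert est.cycles == 1.5

    def test_dense_three_crossings(self):
        t = np.linspace(0, 1.0, 2000, endpoint=False)
        contour = 500.0 * np.exp(0.2 * np.sin(2 * np.pi * 2.0 * t))
        est = estimate_cycles(contour, g=500.0, duration=1.0)
        assert est.cycles == 2.0
        assert est.period_T == pytest.approx(0.5)

    def test_sample_on_gmean_counts_positive(self):
        # exactly-g samples take positive sign, so g, -, g, - has 3 changes
        est = estimate_cycles([500.0, 490.0, 500.0, 490.0], g=500.0, duration=1.0)
        assert est.half_cycles == 4

    @pytest.mark.parametrize("k", range(1, 21))
    def test_exact_on_log_sinusoids(self, k):
        duration = 2.0
        t = np.arange(0, duration, 0.001)
        contour = 1500.0 * np.exp(0.25 * np.sin(2 * np.pi * k * t / duration))
        smoothed = block_smooth(contour, 40)
        est = estimate_cycles(smoothed, g=1500.0, duration=duration)
        assert est.cycles == k
        assert est.period_T == pytest.approx(duration / k)


class TestTriangleContour:
    def test_zero_scale_constant_at_g(self):
        spec = TriangleSpec(g=1200.0, r=0.5, period_T=0.25, scale_x=0.0)
        out = triangle_contour(spec, 1.0)
        assert np.allclose(out.freqs, 1200.0)

    def test_full_scale_extremes(self):
        r = math.log(4 / 3)
        spec = TriangleSpec(g=1200.0, r=r, period_T=0.5, start_phase=0.0, scale_x=1.0)
        out = triangle_contour(spec, 1.0)
        assert out.freqs[0] == pytest.approx(1600.0)
        assert out.freqs[250] == pytest.approx(900.0)  # t = T/2

    def test_half_scale_peak(self):
        r = math.log(4 / 3)
        spec = TriangleSpec(g=1200.0, r=r, period_T=0.5, scale_x=0.5)
        out = triangle_contour(spec, 1.0)
        assert out.freqs[0] == pytest.approx(1200.0 * (4 / 3) ** 0.5, rel=1e-9)

    def test_normalised_peak_is_analytic(self):
        expected = (8 / math.pi**2) * (1 + 1 / 9 + 1 / 25 + 1 / 49)
        assert TRIANGLE_PEAK == pytest.approx(expected)
        # the wave attains exactly +/-1 at phase 0 and T/2
        a = triangle_wave(np.array([0.0, 0.125]), period_T=0.25)
        assert a == pytest.approx([1.0, -1.0])

    @pytest.mark.parametrize("phase", [0.0, 0.2, 0.77])
    def test_gmean_matches_g_over_full_periods(self, phase):
        spec = TriangleSpec(g=1500.0, r=0.4, period_T=0.25, start_phase=phase)
        out = triangle_contour(spec, 1.0)  # 4 full periods
        assert abs(geometric_mean(out) - 1500.0) / 1500.0 < 1e-6

    def test_gmean_deviation_shrinks_with_cycle_count(self):
        # odd half-cycle counts leave a bias that declines as cycles grow
        devs = []
        for n_half in (3, 7, 15):
            duration = n_half * 0.125  # T/2 = 0.125 s
            spec = TriangleSpec(g=1500.0, r=0.4, period_T=0.25, start_phase=0.3)
            out = triangle_contour(spec, duration)
            devs.append(abs(geometric_mean(out) - 1500.0))
        assert devs[0] > devs[1] > devs[2]
        assert devs[0] > 1e-3  # genuinely nonzero for few cycles

    def test_log_range_is_2xr(self):
        r, x = 0.35, 0.6
        spec = TriangleSpec(g=1500.0, r=r, period_T=0.2, scale_x=x)
        out = triangle_contour(spec, 1.0)
        log_dev = np.log(out.freqs / 1500.0)
        assert log_dev.max() - log_dev.min() == pytest.approx(2 * x * r, rel=1e-6)

    def test_duration_below_frame_period(self):
        spec = TriangleSpec(g=1500.0, r=0.4, period_T=0.25)
        with pytest.raises(ValueError):
            triangle_contour(spec, 0.0005)


class TestFlattenAmplitude:
    def test_constant_unchanged(self):
        out = flatten_amplitude(track([500.0, 500.0], amps=[0.4, 0.4]))
        assert np.allclose(out.amps, 0.4)

    def test_rms_value(self):
        out = flatten_amplitude(track([500.0, 500.0], amps=[3.0, 4.0]))
        assert np.allclose(out.amps, math.sqrt(12.5))

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning):
            out = flatten_amplitude(track([500.0, 500.0], amps=[0.0, 0.0]))
        assert np.allclose(out.amps, 0.0)

    def test_freqs_unchanged(self, random_track):
        out = flatten_amplitude(random_track)
        assert np.array_equal(out.freqs, random_track.freqs)


class TestMinSeparation:
    def test_satisfied(self):
        assert check_min_separation(track([500.0] * 5), track([600.0] * 5)) == []

    def test_all_violated(self):
        out = check_min_separation(track([500.0] * 5), track([560.0] * 5))
        assert out == [0, 1, 2, 3, 4]

    def test_length_mismatch(self):
        with pytest.raises(InvalidTrackError):
            check_min_separation(track([500.0] * 4), track([600.0] * 5))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    logs=st.lists(st.floats(min_value=5.3, max_value=8.0), min_size=2, max_size=50),
    x=st.floats(min_value=0.0, max_value=1.0),
)
def test_scaling_properties_hold_for_arbitrary_tracks(logs, x):
    """Geometric-mean preservation and log-linearity over arbitrary contours."""
    t = track(np.exp(np.asarray(logs)))
    g = geometric_mean(t)
    out = scale_depth(t, x)
    assert abs(geometric_mean(out) - g) / g < 1e-9
    assert np.allclose(np.log(out.freqs / g), x * np.log(t.freqs / g), atol=1e-9)
    inv = invert_about_gmean(t)
    assert abs(geometric_mean(inv) - g) / g < 1e-9
    assert np.allclose(invert_about_gmean(inv).freqs, t.freqs, rtol=1e-9)
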