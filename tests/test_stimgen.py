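"""Ring geometry, colorimetry and rendered-frame invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssmvep import stimgen as sg


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

class TestOuterRadii:
    @pytest.mark.parametrize("n,r_max,expected", [
        (1, 100.0, [50.0]),
        (2, 100.0, [25.0, 75.0]),
    ])
    def test_small_cases(self, n, r_max, expected):
        assert sg.compute_outer_radii(n, r_max) == pytest.approx(expected)

    def test_matches_arithmetic_sequence_formula(self):
        # independent term-by-term evaluation of (2i-1) r_max / (2n)
        n, r_max = 4, 200.0
        expected = [(2 * i - 1) * r_max / (2 * n) for i in range(1, n + 1)]
        radii = sg.compute_outer_radii(n, r_max)
        assert radii == pytest.approx(expected)
        assert np.all(np.diff(radii) > 0)
        assert radii[-1] == pytest.approx((2 * n - 1) * r_max / (2 * n))
        assert radii[-1] < r_max

    @pytest.mark.parametrize("n,r_max", [(0, 100), (-1, 100), (3, 0), (3, -5)])
    def test_domain_errors(self, n, r_max):
        with pytest.raises(ValueError):
            sg.compute_outer_radii(n, r_max)


class TestInnerRadii:
    def test_zero_area_limit(self):
        # C -> 0+ collapses the band width to zero
        inner = sg.compute_inner_radii(np.array([50.0]), 1e-9)
        assert inner[0] == pytest.approx(50.0, rel=1e-6)

    def test_unit_ratio_splits_each_cell_evenly(self):
        # C = 1: band area equals gap area within every annular cell
        outer = np.array([25.0, 75.0])
        inner = sg.compute_inner_radii(outer, 1.0)
        prev = np.array([0.0, 25.0])
        band = outer**2 - inner**2
        gap = inner**2 - prev**2
        assert band == pytest.approx(gap)

    def test_realized_ratio_by_pixel_count(self):
        geom = sg.ring_geometry(4, 200.0, 0.6)
        measured = sg.measure_area_ratio(geom, canvas_px=512)
        assert measured == pytest.approx(0.6, rel=0.02)

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            sg.compute_inner_radii(np.array([50.0]), -0.1)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(n=st.integers(1, 12), C=st.floats(0.1, 1.5))
    def test_pixel_count_matches_C_across_parameter_space(self, n, C):
        geom = sg.ring_geometry(n, 256.0, C)
        assert sg.measure_area_ratio(geom, canvas_px=512) == pytest.approx(C, rel=0.02)


# ---------------------------------------------------------------------------
# colorimetry
# ---------------------------------------------------------------------------

class TestLuminance:
    def test_black_is_zero(self):
        assert sg.perceived_luminance((0, 0, 0), C1=0.7) == 0.0

    def test_rec709_coefficients(self):
        # recover each coefficient from a single-channel probe
        for i, coeff in enumerate([0.2126, 0.7152, 0.0722]):
            rgb = [0.0, 0.0, 0.0]
            rgb[i] = 1.0
            assert sg.perceived_luminance(rgb, C1=1.0) == pytest.approx(coeff)

    def test_red_green_equiluminance_closed_form(self):
        # solve L(0, g*, 0) = L(255, 0, 0) independently: g* = 255*0.2126/0.7152
        g_star = 255.0 * 0.2126 / 0.7152
        assert sg.perceived_luminance((0, g_star, 0)) == pytest.approx(
            sg.perceived_luminance((255, 0, 0)))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sg.perceived_luminance((0, 300, 0))


class TestMatchLuminance:
    def test_black_reference(self):
        state = sg.match_luminance((0, 0, 0), "green")
        assert state.rgb == (0.0, 0.0, 0.0)
        assert state.perceived_luminance == 0.0

    def test_red_to_green_closed_form(self):
        r = 170.0
        state = sg.match_luminance((r, 0, 0), "green")
        assert state.rgb[1] == pytest.approx(r * 0.2126 / 0.7152)
        assert state.perceived_luminance == pytest.approx(
            sg.perceived_luminance((r, 0, 0)), rel=0.005)

    def test_gamut_error_reports_maximum(self):
        # white at full brightness exceeds what pure green can deliver
        with pytest.raises(sg.GamutError) as err:
            sg.match_luminance((255, 255, 255), "green")
        assert err.value.max_achievable == pytest.approx(0.7 * 0.7152 * 255)

    def test_gamut_safe_solver_desaturates(self):
        target = 0.7 * 0.9 * 255  # above pure green, below white
        rgb = sg.solve_luminance_on_hue(target, "green")
        assert rgb[1] == pytest.approx(255.0)
        assert rgb[0] == pytest.approx(rgb[2])
        assert sg.perceived_luminance(rgb) == pytest.approx(target)


class TestColorWaveform:
    def test_starts_at_zero_and_peaks_mid_cycle(self):
        f, r_max = 3.0, 200.0
        assert sg.color_waveform(0.0, f, r_max) == 0.0
        assert sg.color_waveform(1 / (2 * f), f, r_max) == pytest.approx(r_max)

    def test_pointwise_against_direct_formula(self):
        f, r_max = 4.0, 255.0
        t = np.linspace(0, 1 / f, 60, endpoint=False)
        expected = 0.5 * r_max * (1 - np.cos(2 * np.pi * f * t))
        assert sg.color_waveform(t, f, r_max) == pytest.approx(expected)

    def test_periodicity(self):
        f = 3.5
        t = np.linspace(0, 0.9, 37)
        assert sg.color_waveform(t + 1 / f, f, 100.0) == pytest.approx(
            sg.color_waveform(t, f, 100.0))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _pixel_mean_luminance(seq, config):
    geom = config.geometry
    radius = sg._radius_grid(config.canvas_px)
    disc = radius < geom.disc_radius
    return np.array([
        sg.perceived_luminance(np.clip(frame[disc], 0, 255), config.C1).mean()
        for frame in seq.frames])


class TestRenderCycle:
    def test_single_color_has_static_masks(self):
        cfg = sg.StimulusConfig(paradigm="single_color", canvas_px=96,
                                frame_rate_hz=30.0)
        seq = sg.render_cycle(cfg)
        # no motion: every frame's disc luminance is an affine image of the
        # same band-coverage field, so min-max normalization recovers an
        # identical spatial map across the whole cycle (disc eroded by 2 px
        # to exclude pixels blended with the surround)
        disc = sg._radius_grid(cfg.canvas_px) < cfg.geometry.disc_radius - 2.0

        def coverage_map(frame):
            lum = (frame @ sg.REC709_COEFFS)[disc]
            return (lum.max() - lum) / (lum.max() - lum.min())

        ref = coverage_map(seq.frames[0])
        for frame in seq.frames[1:]:
            np.testing.assert_allclose(coverage_map(frame), ref, atol=1e-3)

    def test_bimodal_periodicity_at_3hz_60fps(self):
        cfg = sg.StimulusConfig(paradigm="bimodal", frequency_hz=3.0,
                                frame_rate_hz=60.0, canvas_px=96)
        seq = sg.render_cycle(cfg, min_periods=2)
        assert seq.n_frames == 40 and seq.n_periods == 2
        np.testing.assert_allclose(seq.frames[20], seq.frames[0], atol=1e-4)

    def test_bimodal_area_ratio_and_luminance_ripple(self):
        cfg = sg.StimulusConfig(paradigm="bimodal", frequency_hz=3.0,
                                brightness_level="medium", area_ratio_C=0.6,
                                canvas_px=256, frame_rate_hz=60.0)
        seq = sg.render_cycle(cfg)
        lum = _pixel_mean_luminance(seq, cfg)
        assert (lum.max() - lum.min()) / lum.mean() <= 0.01
        # zero-displacement frame realizes C by pixel count
        assert sg.measure_area_ratio(cfg.geometry, 512) == pytest.approx(0.6, rel=0.02)

    def test_frame_rate_below_nyquist_rejected(self):
        with pytest.raises(ValueError):
            sg.StimulusConfig(frequency_hz=4.0, frame_rate_hz=6.0)

    def test_canvas_too_small_rejected(self):
        with pytest.raises(ValueError):
            sg.StimulusConfig(canvas_px=64, r_max=100.0)


class TestComposeLayout:
    def test_default_offsets_place_targets_at_printed_positions(self):
        cfgs = [sg.StimulusConfig(frequency_hz=f, canvas_px=64,
                                  frame_rate_hz=30.0, paradigm="single_color")
                for f in (4.0, 4.5, 3.0, 3.5)]
        seq = sg.compose_layout(cfgs, canvas_px=(600, 840))
        # vertical targets 240 px above/below center, horizontal 360 px aside
        assert seq.frames.shape[1:] == (600, 840, 3)
        center = np.array([300, 420])
        for dy, dx in [(-240, 0), (240, 0), (0, -360), (0, 360)]:
            y, x = center + (dy, dx)
            patch = seq.frames[0, y - 30:y + 30, x - 30:x + 30]
            assert not np.allclose(patch, 128.0)  # a target sits there

    def test_single_target_at_center_matches_render_cycle(self):
        cfg = sg.StimulusConfig(frequency_hz=3.0, canvas_px=64,
                                frame_rate_hz=30.0)
        seq = sg.compose_layout([cfg], canvas_px=(64, 64), offsets=[(0, 0)])
        direct = sg.render_cycle(cfg)
        np.testing.assert_allclose(seq.frames[:direct.n_frames], direct.frames,
                                   atol=1e-5)

    def test_overlap_rejected(self):
        cfgs = [sg.StimulusConfig(frequency_hz=f, canvas_px=64, frame_rate_hz=30.0)
                for f in (3.0, 3.5)]
        with pytest.raises(sg.LayoutError):
            sg.compose_layout(cfgs, canvas_px=(200, 200),
                              offsets=[(0, 0), (10, 10)])

    def test_pixel_traces_carry_target_frequencies(self):
        freqs = (3.0, 3.5, 4.0, 4.5)
        cfgs = [sg.StimulusConfig(frequency_hz=f, canvas_px=48, frame_rate_hz=36.0,
                                  paradigm="single_color") for f in freqs]
        offsets = [(-56, 0), (56, 0), (0, -56), (0, 56)]
        seq = sg.compose_layout(cfgs, canvas_px=(160, 160), offsets=offsets)
        fps, n = seq.frame_rate_hz, seq.n_frames
        grid = np.fft.rfftfreq(n, d=1.0 / fps)
        for f, (dy, dx) in zip(freqs, offsets):
            y, x = 80 + dy, 80 + dx
            trace = seq.frames[:, y, x, 1] - seq.frames[:, y, x, 1].mean()
            peak = grid[1 + np.argmax(np.abs(np.fft.rfft(trace))[1:])]
            assert peak == pytest.approx(f, abs=grid[1] / 2 + 1e-9)
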