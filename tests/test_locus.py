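"""Telomere scoring, line profiles, locus tracking, burst cycles and
treatment-response testing."""

import numpy as np
import pytest

from rloopkit import (
    ImageStack,
    detect_fluctuation_cycles,
    fraction_above_background,
    line_profile,
    segment_marker_foci,
    simulate_locus_timelapse,
    simulate_telomere_scene,
    track_locus,
    treatment_response_test,
)
from rloopkit.locus import LocusError, LocusTrack
from rloopkit.simulate import _gaussian_blob
from rloopkit.stacks import rectangle_roi


class TestSegmentation:
    def test_forty_telomeres_segmented(self):
        marker, _, _, truth = simulate_telomere_scene(
            n_telomeres=40, n_with_sensor=0, seed=4
        )
        objects = segment_marker_foci(marker)
        assert len(objects) == 40

    def test_blank_stack_gives_no_objects(self):
        blank = ImageStack(data=np.zeros((6, 48, 48), np.uint16), axes="zyx")
        assert segment_marker_foci(blank) == []

    def test_oversized_component_rejected_by_max_size(self):
        """A blob whose wavelet support exceeds 50 voxels is dropped,
        as two merged foci would be."""
        lam = np.full((12, 64, 64), 20.0)
        lam += _gaussian_blob((12, 64, 64), (32.0, 32.0, 6.0), (3.0, 3.0, 2.0), 8e5)
        rng = np.random.default_rng(0)
        data = np.clip(np.rint(rng.poisson(lam)), 0, 65535).astype(np.uint16)
        big = ImageStack(data=data, axes="zyx")
        assert segment_marker_foci(big) == []


class TestFractionAboveBackground:
    def test_uniform_sensor_fraction_zero(self):
        marker, _, bg_roi, _ = simulate_telomere_scene(
            n_telomeres=30, n_with_sensor=0, seed=5
        )
        uniform = ImageStack(
            data=np.random.default_rng(1).poisson(100.0, marker.data.shape).astype(np.uint16),
            axes="zyx",
        )
        objects = segment_marker_foci(marker)
        assert fraction_above_background(objects, uniform, bg_roi) == 0.0

    def test_constructed_32_percent(self):
        marker, sensor, bg_roi, _ = simulate_telomere_scene(
            n_telomeres=100, n_with_sensor=32, sensor_contrast=10.0, seed=6
        )
        objects = segment_marker_foci(marker)
        assert len(objects) == 100
        assert fraction_above_background(objects, sensor, bg_roi) == pytest.approx(0.32)

    def test_monotone_in_k_sd_and_infinite_limit(self):
        marker, sensor, bg_roi, _ = simulate_telomere_scene(
            n_telomeres=50, n_with_sensor=20, seed=7
        )
        objects = segment_marker_foci(marker)
        fracs = [
            fraction_above_background(objects, sensor, bg_roi, k_sd=k)
            for k in (0.0, 2.0, 10.0, np.inf)
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] == 0.0

    def test_empty_object_list_is_undefined(self):
        marker, sensor, bg_roi, _ = simulate_telomere_scene(
            n_telomeres=5, n_with_sensor=0, seed=8
        )
        assert fraction_above_background([], sensor, bg_roi) is None

    def test_null_fraction_stays_near_gaussian_tail(self):
        """With sensor independent of telomeres the expected fraction at
        k_sd = 2 is at most ~0.023 (one-sided Gaussian tail), and object
        averaging pushes it far lower."""
        marker, sensor, bg_roi, _ = simulate_telomere_scene(
            n_telomeres=100, n_with_sensor=0, seed=9
        )
        objects = segment_marker_foci(marker)
        frac = fraction_above_background(objects, sensor, bg_roi)
        n = len(objects)
        assert frac <= 0.023 + 3 * np.sqrt(0.023 * 0.977 / n)


class TestLineProfile:
    def test_constant_image(self):
        img = ImageStack(data=np.full((32, 32), 9, np.uint16), axes="yx")
        prof = line_profile(img, (2, 5), (25, 5))
        assert np.allclose(prof, 9.0)

    def test_horizontal_ramp_is_linear(self):
        ramp = np.tile(np.arange(40, dtype=float), (20, 1))
        img = ImageStack(data=ramp, axes="yx", bit_depth=32)
        prof = line_profile(img, (3, 10), (30, 10))[0]
        assert np.allclose(prof, np.linspace(3, 30, len(prof)))

    def test_gaussian_spot_peak_at_projection_of_center(self):
        lam = _gaussian_blob((1, 48, 48), (29.0, 20.0, 0.0), (2.0, 2.0, 1.0), 1e4)[0]
        img = ImageStack(data=lam, axes="yx", bit_depth=32)
        prof = line_profile(img, (5, 20), (45, 20))[0]
        assert abs((5 + np.argmax(prof)) - 29) <= 1

    def test_zero_length_segment_rejected(self):
        img = ImageStack(data=np.zeros((8, 8), np.uint16), axes="yx")
        with pytest.raises(LocusError):
            line_profile(img, (3, 3), (3, 3))


class TestTrackLocus:
    def test_static_symmetric_marker_tracked_exactly(self):
        stack, truth = simulate_locus_timelapse(
            n_frames=8, poisson_noise=False, read_noise_sd=0.0,
            shape_zyx=(9, 32, 32), seed=0,
        )
        track = track_locus(stack)
        cx, cy, cz = truth.params["center"]
        err = np.abs(track.positions - np.array([cx, cy, cz])).max()
        assert err <= 0.05

    def test_drifting_marker_followed_within_half_pixel(self):
        stack, truth = simulate_locus_timelapse(
            n_frames=20, drift_px_per_frame=(0.2, 0.0),
            shape_zyx=(7, 48, 48), seed=3,
        )
        track = track_locus(stack)
        expected = truth.params["positions"]
        err = np.abs(track.positions[:, :2] - expected[:, :2]).max()
        assert err <= 0.5

    def test_background_sensor_reads_near_zero(self):
        stack, _ = simulate_locus_timelapse(
            sensor_on_level=0.0, n_frames=10, shape_zyx=(7, 32, 32), seed=2
        )
        track = track_locus(stack)
        # locally background-subtracted means sit within shot noise of 0
        assert np.abs(track.sensor_series).max() <= 5.0


class TestFluctuationCycles:
    def test_45s_bursts_sampled_at_8s(self):
        stack, truth = simulate_locus_timelapse(
            burst_period_s=45.0, burst_duration_s=20.0,
            n_frames=75, dt_s=8.0, shape_zyx=(7, 32, 32), seed=5,
        )
        track = track_locus(stack)
        peaks, period = detect_fluctuation_cycles(track, smooth_window=3)
        assert period is not None
        assert 37.0 <= period <= 53.0
        assert len(peaks) >= len(truth.burst_times) - 1

    def test_noisefree_series_recovers_burst_count_exactly(self):
        stack, truth = simulate_locus_timelapse(
            burst_period_s=45.0, burst_duration_s=20.0,
            n_frames=75, dt_s=8.0, shape_zyx=(7, 32, 32),
            poisson_noise=False, read_noise_sd=0.0, seed=5,
        )
        track = track_locus(stack)
        peaks, _ = detect_fluctuation_cycles(track, smooth_window=3)
        assert len(peaks) == len(truth.burst_times)

    def test_constant_series_has_no_peaks(self):
        track = LocusTrack(
            times_s=np.arange(10.0),
            positions=np.zeros((10, 3)),
            sensor_series=np.full(10, 3.0),
            marker_series=np.ones(10),
            lost_frames=[],
        )
        peaks, period = detect_fluctuation_cycles(track)
        assert len(peaks) == 0 and period is None

    def test_single_burst_gives_one_peak_no_period(self):
        stack, truth = simulate_locus_timelapse(
            burst_period_s=400.0, burst_duration_s=40.0,
            n_frames=55, dt_s=8.0, shape_zyx=(7, 32, 32), seed=6,
        )
        assert len(truth.burst_times) == 1
        track = track_locus(stack)
        peaks, period = detect_fluctuation_cycles(track, smooth_window=3)
        assert len(peaks) == 1 and period is None


class TestTreatmentResponse:
    def test_identical_pre_and_post_not_significant(self, rng):
        pre = rng.normal(1000, 80, 30)
        post = np.tile(pre[:, None], (1, 4)) + rng.normal(0, 1e-6, (30, 4))
        p = treatment_response_test(pre, post)
        assert np.all(p > 0.9)

    def test_drb_style_decay_significant_from_first_post_point(self, rng):
        pre = rng.normal(1000, 100, 35)
        t = np.arange(1, 13) * 600.0  # 10-min spacing
        post = pre[:, None] * np.exp(-t / 360.0) + rng.normal(0, 100, (35, 12))
        p = treatment_response_test(pre, post)
        assert np.all(p[0:] < 0.05)

    def test_washout_restores_nonsignificance(self, rng):
        pre = rng.normal(1000, 100, 35)
        washout = rng.normal(1000, 100, (35, 2))
        p = treatment_response_test(pre, washout)
        assert np.all(p > 0.05)

    def test_single_cell_names_paired_alternative(self):
        with pytest.raises(LocusError, match="paired"):
            treatment_response_test(np.array([1.0]), np.array([[1.0]]))
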