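"""FRAP: registration, signal extraction, double normalization,
time-to-fraction kinetics, population labels and fold ratios."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rloopkit import (
    CircleRoi,
    FrapExperiment,
    ImageStack,
    NormalizedFrapCurve,
    classify_population,
    compute_kinetics,
    fold_over_reference,
    mean_curve_with_sd,
    measure_frap_signals,
    normalize_frap,
    plateau,
    pointwise_ttest_curve,
    register_frames,
    time_to_fraction,
)
from rloopkit.frap import FrapError, round_half_up
from rloopkit.simulate import FrapSimConfig, simulate_frap_experiment, simulate_frap_movie
from rloopkit.stacks import rectangle_roi


def _exp_curve(k, n_pre=5, n_post=120, dt=0.3):
    times = np.arange(n_pre + n_post) * dt
    values = np.ones(n_pre + n_post)
    post_t = np.arange(n_post) * dt
    values[n_pre:] = 1.0 - np.exp(-k * post_t)
    return NormalizedFrapCurve(times_s=times, values=values, n_pre=n_pre)


class TestRegistration:
    def test_identical_frames_zero_shift(self, rng):
        frame = rng.normal(100, 10, (48, 48))
        st_ = ImageStack(data=np.stack([frame] * 4), axes="tyx", bit_depth=32)
        _, shifts = register_frames(st_)
        assert shifts == [(0, 0)] * 4

    def test_known_translation_recovered(self, rng):
        base = rng.normal(100, 15, (64, 64))
        moved = np.roll(np.roll(base, -2, axis=0), 3, axis=1)  # (dx, dy) = (3, -2)
        st_ = ImageStack(data=np.stack([base, moved]), axes="tyx", bit_depth=32)
        aligned, shifts = register_frames(st_)
        assert shifts[1] == (3, -2)
        interior = (slice(8, -8), slice(8, -8))
        assert np.allclose(aligned.data[1][interior], base[interior])

    def test_constant_frames_warn_and_stay(self):
        st_ = ImageStack(data=np.zeros((3, 16, 16)), axes="tyx", bit_depth=32)
        with pytest.warns(UserWarning, match="degenerate"):
            _, shifts = register_frames(st_)
        assert shifts == [(0, 0)] * 3

    def test_noise_frames_bounded_by_search_radius(self, rng):
        frames = rng.normal(0, 1, (4, 40, 40))
        st_ = ImageStack(data=frames, axes="tyx", bit_depth=32)
        _, shifts = register_frames(st_, max_shift_px=5)
        for dx, dy in shifts:
            assert abs(dx) <= 5 and abs(dy) <= 5


class TestMeasureSignals:
    def _rois(self):
        return (
            CircleRoi(center=(40, 48), diameter_px=25),
            rectangle_roi(8, 8, 72, 88, label="cell"),
            rectangle_roi(82, 4, 94, 92, label="background"),
        )

    def test_uniform_frames_give_constant_triple(self):
        bleach, cell, bg = self._rois()
        st_ = ImageStack(data=np.full((6, 96, 96), 37, np.uint16), axes="tyx")
        exp = measure_frap_signals(st_, bleach, cell, bg, n_pre=2)
        for series in (exp.roi_series, exp.background_series, exp.reference_series):
            assert np.allclose(series, 37.0)

    def test_reference_tracks_acquisition_decay_exactly(self):
        cfg = FrapSimConfig(
            acquisition_bleach_rate=0.004, noise=False, background_photons=0.0,
            reference_level_photons=512.0, seed=0,
        )
        movie, rois, _ = simulate_frap_movie(cfg, shape_yx=(96, 96))
        exp = measure_frap_signals(
            movie, rois["bleach"], rois["cell"], rois["background"], n_pre=5
        )
        decay = (1 - 0.004) ** np.arange(125)
        ratio = exp.reference_series / exp.reference_series[0]
        assert np.allclose(ratio, decay, atol=2e-3)  # integer quantisation only

    def test_zero_valued_background_region(self):
        bleach, cell, bg = self._rois()
        frames = np.full((3, 96, 96), 50, np.uint16)
        frames[:, :, 80:] = 0
        exp = measure_frap_signals(
            ImageStack(data=frames, axes="tyx"), bleach, cell, bg, n_pre=1
        )
        assert np.allclose(exp.background_series, 0.0)

    def test_overlapping_background_and_cell_rejected(self):
        bleach, cell, _ = self._rois()
        bad_bg = rectangle_roi(60, 60, 90, 90)
        st_ = ImageStack(data=np.zeros((3, 96, 96), np.uint16), axes="tyx")
        with pytest.raises(FrapError, match="overlap"):
            measure_frap_signals(st_, bleach, cell, bad_bg, n_pre=1)


class TestNormalization:
    def test_anchors_exact_on_noisy_experiment(self):
        exp, _ = simulate_frap_experiment(FrapSimConfig(seed=9))
        curve = normalize_frap(exp)
        assert curve.values[:5].mean() == pytest.approx(1.0, abs=1e-12)
        assert curve.values[5] == 0.0

    def test_bleaching_correction_recovers_ground_truth(self):
        cfg = FrapSimConfig(noise=False, acquisition_bleach_rate=0.005, seed=0)
        exp, truth = simulate_frap_experiment(cfg)
        curve = normalize_frap(exp)
        assert np.abs(curve.post_values - truth.true_recovery).max() <= 1e-6

    def test_nonpositive_reference_raises(self):
        exp = FrapExperiment(
            times_s=np.arange(4.0),
            roi_series=np.array([5.0, 5.0, 1.0, 2.0]),
            background_series=np.array([1.0, 1.0, 1.0, 1.0]),
            reference_series=np.array([5.0, 1.0, 5.0, 5.0]),  # hits zero after bg
            n_pre=2,
        )
        with pytest.raises(FrapError, match="reference"):
            normalize_frap(exp)

    def test_no_bleach_is_degenerate(self):
        n = np.ones(10)
        exp = FrapExperiment(
            times_s=np.arange(10.0),
            roi_series=n * 5,
            background_series=n * 0,
            reference_series=n * 5,
            n_pre=3,
        )
        with pytest.raises(FrapError, match="bleach"):
            normalize_frap(exp)


class TestKinetics:
    def test_t50_and_t80_of_single_exponential(self):
        k = math.log(2) / 25.0
        curve = _exp_curve(k, n_post=600, dt=0.5)
        assert time_to_fraction(curve, 0.5) == pytest.approx(25.0, abs=0.25)
        assert time_to_fraction(curve, 0.8) == pytest.approx(math.log(5) / k, abs=0.25)

    def test_plateau_below_fraction_never_crosses(self):
        times = np.arange(125) * 0.3
        values = np.ones(125)
        values[5:] = 0.65 * (1 - np.exp(-0.5 * (times[5:] - times[5])))
        curve = NormalizedFrapCurve(times_s=times, values=values, n_pre=5)
        assert time_to_fraction(curve, 0.8) is None
        assert plateau(curve, 10) == pytest.approx(0.65, abs=0.01)

    def test_fraction_must_be_in_open_unit_interval(self):
        curve = _exp_curve(0.1)
        with pytest.raises(FrapError):
            time_to_fraction(curve, 1.0)

    def test_plateau_window_sizes(self):
        curve = _exp_curve(5.0)  # fast full recovery
        assert plateau(curve, 10) == pytest.approx(1.0, abs=1e-6)
        full = plateau(curve, 120)
        assert full == pytest.approx(curve.post_values.mean())
        with pytest.raises(FrapError):
            plateau(curve, 121)

    def test_classification_examples(self):
        fast = compute_kinetics(_exp_curve(math.log(5) / 8.1))
        assert fast.t80_s == pytest.approx(8.1, abs=0.2)
        assert classify_population(fast) == "fast"
        slow_curve_vals = np.ones(125)
        slow_curve_vals[5:] = 0.65
        slow = compute_kinetics(
            NormalizedFrapCurve(
                times_s=np.arange(125) * 0.3, values=slow_curve_vals, n_pre=5
            )
        )
        assert slow.t80_s is None
        assert classify_population(slow) == "slow"


class TestFoldOverReference:
    @pytest.mark.parametrize(
        "target,refs,expected",
        [
            (135.0, [8.0], 16.875),
            (8.1, [2.4, 2.1], 3.6),
            (4.0, [0.6, 0.6], 6.67),
        ],
    )
    def test_printed_fold_values(self, target, refs, expected):
        assert round_half_up(fold_over_reference(target, refs), 2) == pytest.approx(
            expected, abs=0.005
        )

    def test_invalid_inputs(self):
        with pytest.raises(FrapError):
            fold_over_reference(10.0, [])
        with pytest.raises(FrapError):
            fold_over_reference(-1.0, [2.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        scale=st.floats(1e-3, 1e3),
        target=st.floats(0.1, 500),
        ref=st.floats(0.1, 500),
    )
    def test_scale_invariance(self, scale, target, ref):
        f1 = fold_over_reference(target, [ref])
        f2 = fold_over_reference(target * scale, [ref * scale])
        assert f2 == pytest.approx(f1, rel=1e-9)


class TestCurveEnsembles:
    def test_identical_curves_have_zero_sd(self):
        curves = [_exp_curve(0.2) for _ in range(5)]
        mean, sd = mean_curve_with_sd(curves)
        assert np.allclose(mean.values, curves[0].values)
        assert np.allclose(sd, 0.0)

    def test_two_point_sd_closed_form(self):
        a = _exp_curve(0.2)
        b = _exp_curve(0.2)
        a.values = a.values * 0 + 0.4
        b.values = b.values * 0 + 0.6
        mean, sd = mean_curve_with_sd([a, b])
        assert mean.values[10] == pytest.approx(0.5)
        assert sd[10] == pytest.approx(0.1414, abs=1e-3)

    def test_single_curve_sd_is_none(self):
        _, sd = mean_curve_with_sd([_exp_curve(0.2)])
        assert sd is None

    def test_mean_of_noisy_curves_tracks_truth(self):
        cfgs = [FrapSimConfig(fractions=[(1.0, 0.3)], seed=s) for s in range(25)]
        curves = [normalize_frap(simulate_frap_experiment(c)[0]) for c in cfgs]
        truth = simulate_frap_experiment(cfgs[0])[1]
        mean, sd = mean_curve_with_sd(curves)
        se = sd[5:] / math.sqrt(25)
        resid = np.abs(mean.values[5:] - truth.true_recovery)
        assert (resid <= 4 * se + 1e-9).mean() > 0.95


class TestPointwiseTtest:
    def test_identical_groups_p_near_one(self):
        g = [_exp_curve(0.2) for _ in range(3)]
        _, p = pointwise_ttest_curve(g, [c for c in g])
        assert np.all(p > 0.99)

    def test_separated_groups_highly_significant(self, rng):
        def noisy(level):
            c = _exp_curve(0.2)
            c.values = np.full_like(c.values, level) + rng.normal(0, 0.02, len(c.values))
            return c

        ga = [noisy(0.2) for _ in range(20)]
        gb = [noisy(0.8) for _ in range(20)]
        _, p = pointwise_ttest_curve(ga, gb)
        assert np.all(p < 1e-3)

    def test_single_frame_matches_direct_welch_oracle(self, rng):
        ga = [_exp_curve(0.2) for _ in range(4)]
        gb = [_exp_curve(0.2) for _ in range(5)]
        for c in ga + gb:
            c.values = c.values + rng.normal(0, 0.05, len(c.values))
        times, p = pointwise_ttest_curve(ga, gb)
        j = 30
        a = np.array([c.values[j] for c in ga])
        b = np.array([c.values[j] for c in gb])
        # direct Welch formula
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        from scipy.stats import t as tdist

        p_oracle = 2 * tdist.sf(abs(t), df)
        assert p[j] == pytest.approx(p_oracle, rel=1e-9)

    def test_too_few_curves_rejected(self):
        with pytest.raises(FrapError):
            pointwise_ttest_curve([_exp_curve(0.2)], [_exp_curve(0.2)] * 2)
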