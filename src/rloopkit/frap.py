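"""FRAP measurement, double normalization and recovery kinetics.

The measurement triple per frame is: mean intensity in the bleached
ROI, mean extracellular background, and the mean of the labelled
nucleus excluding the bleach ROI (the reference, which tracks the loss
of fluorescence due to continuous imaging).  Double normalization
background-subtracts both signals, divides out the reference decay and
anchors the curve so that the pre-bleach mean is exactly 1 and the
first post-bleach value exactly 0:

    b(t) = roi(t) - bg(t)
    r(t) = ref(t) - bg(t)
    x(t) = b(t) * mean_pre(r) / r(t)
    N(t) = (x(t) - x(t0+)) / (mean_pre(x) - x(t0+))

Kinetic readouts (t50, t80) are times after the bleach at which the
normalized curve first reaches the given fraction of the pre-bleach
level, read from the curve by linear interpolation — not fitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats

from .stacks import CircleRoi, ImageStack, PolygonRoi


class FrapError(ValueError):
    """Raised for invalid or degenerate FRAP inputs."""


@dataclass
class FrapExperiment:
    """Raw per-frame measurement triple plus acquisition timing."""

    times_s: np.ndarray
    roi_series: np.ndarray
    background_series: np.ndarray
    reference_series: np.ndarray
    n_pre: int
    bleach_roi: CircleRoi | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.roi_series = np.asarray(self.roi_series, dtype=float)
        self.background_series = np.asarray(self.background_series, dtype=float)
        self.reference_series = np.asarray(self.reference_series, dtype=float)
        n = len(self.times_s)
        if not (
            len(self.roi_series)
            == len(self.background_series)
            == len(self.reference_series)
            == n
        ):
            raise FrapError("all series must have the same length")
        if not (1 <= self.n_pre < n):
            raise FrapError("need 1 <= n_pre < number of frames")
        if np.any(np.diff(self.times_s) <= 0):
            raise FrapError("times must be strictly increasing")


@dataclass
class NormalizedFrapCurve:
    """Normalized recovery: pre-bleach mean 1, first post-bleach 0."""

    times_s: np.ndarray
    values: np.ndarray
    n_pre: int

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times_s) != len(self.values):
            raise FrapError("times and values must have the same length")

    @property
    def post_times_s(self) -> np.ndarray:
        """Times relative to the first post-bleach frame."""
        return self.times_s[self.n_pre :] - self.times_s[self.n_pre]

    @property
    def post_values(self) -> np.ndarray:
        return self.values[self.n_pre :]


@dataclass
class FrapKinetics:
    """Summary kinetics for one normalized curve."""

    t50_s: float | None
    t80_s: float | None
    plateau: float
    population: str | None = None  # "fast" | "slow" | "reference"
    fold_over_reference_50: float | None = None
    fold_over_reference_80: float | None = None


# ---------------------------------------------------------------------------
# Frame registration (translation-only)
# ---------------------------------------------------------------------------


def register_frames(
    timelapse: ImageStack, max_shift_px: int = 10
) -> tuple[ImageStack, list[tuple[int, int]]]:
    """Align a 2D+t stack to its first frame by integer-pixel translation.

    Each frame's translation (dx, dy) relative to the first frame is
    estimated as the zero-normalized cross-correlation peak within
    ``+-max_shift_px``; the aligned stack shifts each frame back by
    that amount.  Constant (degenerate) frames get zero shift with a
    warning.
    """
    if "t" not in timelapse.axes or timelapse.axes.replace("t", "") != "yx":
        raise FrapError(f"expected a 2D+t stack, got axes {timelapse.axes!r}")
    movie = timelapse.data.astype(float)
    ref = movie[0] - movie[0].mean()
    shifts: list[tuple[int, int]] = []
    aligned = np.empty_like(movie)
    degenerate = ref.std() == 0
    for f in range(movie.shape[0]):
        frame = movie[f] - movie[f].mean()
        if degenerate or frame.std() == 0:
            if f > 0:
                warnings.warn(f"degenerate (constant) frame {f}: zero shift")
            shifts.append((0, 0))
            aligned[f] = movie[f]
            continue
        corr = signal.fftconvolve(frame, ref[::-1, ::-1], mode="same")
        cy, cx = np.array(corr.shape) // 2
        window = corr[
            max(0, cy - max_shift_px) : cy + max_shift_px + 1,
            max(0, cx - max_shift_px) : cx + max_shift_px + 1,
        ]
        iy, ix = np.unravel_index(np.argmax(window), window.shape)
        dy = iy + max(0, cy - max_shift_px) - cy
        dx = ix + max(0, cx - max_shift_px) - cx
        shifts.append((int(dx), int(dy)))
        aligned[f] = ndimage.shift(movie[f], (-dy, -dx), order=0, mode="nearest")
    out = ImageStack(
        data=aligned,
        axes=timelapse.axes,
        voxel_size_um=timelapse.voxel_size_um,
        time_interval_s=timelapse.time_interval_s,
        bit_depth=timelapse.bit_depth,
    )
    return out, shifts


# ---------------------------------------------------------------------------
# Signal extraction and normalization
# ---------------------------------------------------------------------------


def measure_frap_signals(
    timelapse: ImageStack,
    bleach_roi: CircleRoi,
    cell_roi: PolygonRoi,
    background_roi: PolygonRoi,
    n_pre: int,
) -> FrapExperiment:
    """Extract the per-frame measurement triple from a 2D+t stack."""
    if "t" not in timelapse.axes:
        raise FrapError("timelapse needs a t axis")
    shape_yx = (timelapse.extent("y"), timelapse.extent("x"))
    bleach_mask = bleach_roi.mask(shape_yx)
    cell_mask = cell_roi.mask(shape_yx)
    bg_mask = background_roi.mask(shape_yx)
    if (bg_mask & cell_mask).any():
        raise FrapError("background ROI overlaps the cell ROI")
    ref_mask = cell_mask & ~bleach_mask
    if not bleach_mask.any() or not ref_mask.any() or not bg_mask.any():
        raise FrapError("an ROI covers no pixels")
    movie = timelapse.data.astype(float)
    if movie.ndim != 3:
        raise FrapError("expected a single-channel 2D+t stack")
    roi = movie[:, bleach_mask].mean(axis=1)
    bg = movie[:, bg_mask].mean(axis=1)
    ref = movie[:, ref_mask].mean(axis=1)
    return FrapExperiment(
        times_s=timelapse.frame_times_s(),
        roi_series=roi,
        background_series=bg,
        reference_series=ref,
        n_pre=n_pre,
        bleach_roi=bleach_roi,
    )


def normalize_frap(exp: FrapExperiment) -> NormalizedFrapCurve:
    """Double normalization with acquisition-bleaching correction."""
    b = exp.roi_series - exp.background_series
    r = exp.reference_series - exp.background_series
    if np.any(r <= 0):
        raise FrapError(
            "reference minus background is non-positive at some frame; "
            "cannot correct for acquisition bleaching"
        )
    correction = r[: exp.n_pre].mean() / r
    x = b * correction
    x0 = x[exp.n_pre]  # first post-bleach frame
    pre = x[: exp.n_pre].mean()
    if pre == x0:
        raise FrapError("no bleach: pre-bleach mean equals first post-bleach value")
    values = (x - x0) / (pre - x0)
    return NormalizedFrapCurve(times_s=exp.times_s, values=values, n_pre=exp.n_pre)


# ---------------------------------------------------------------------------
# Kinetic readouts
# ---------------------------------------------------------------------------


def time_to_fraction(
    curve: NormalizedFrapCurve, fraction: float, smooth_window: int = 1
) -> float | None:
    """First time after the bleach at which the curve reaches *fraction*.

    Linear interpolation between the bracketing frames; the crossing
    must be confirmed by the next frame also sitting at or above the
    fraction (unless the crossing frame is the last one), which guards
    against single-frame noise spikes.  Time is relative to the first
    post-bleach frame; ``None`` if the level is never reached.
    """
    if not (0 < fraction < 1):
        raise FrapError("fraction must be in (0, 1)")
    t = curve.post_times_s
    v = curve.post_values.copy()
    if smooth_window > 1:
        v = ndimage.uniform_filter1d(v, smooth_window, mode="nearest")
    for i in range(1, len(v)):
        if v[i] >= fraction and v[i - 1] < fraction:
            if i + 1 < len(v) and v[i + 1] < fraction:
                continue
            # linear interpolation between frames i-1 and i
            frac_step = (fraction - v[i - 1]) / (v[i] - v[i - 1])
            return float(t[i - 1] + frac_step * (t[i] - t[i - 1]))
    return None


def plateau(curve: NormalizedFrapCurve, terminal_window: int = 10) -> float:
    """Mean of the last *terminal_window* normalized values."""
    post = curve.post_values
    if terminal_window > len(post):
        raise FrapError("terminal_window exceeds the number of post frames")
    return float(post[-terminal_window:].mean())


def compute_kinetics(
    curve: NormalizedFrapCurve,
    terminal_window: int = 10,
    smooth_window: int = 1,
) -> FrapKinetics:
    """t50, t80 and plateau for one curve (no population label yet)."""
    t50 = time_to_fraction(curve, 0.5, smooth_window)
    t80 = time_to_fraction(curve, 0.8, smooth_window)
    return FrapKinetics(t50_s=t50, t80_s=t80, plateau=plateau(curve, terminal_window))


def classify_population(kin: FrapKinetics, fast_t80_cutoff_s: float = 36.0) -> str:
    """Label a curve fast or slow by its time to 80% recovery.

    Fast iff t80 is defined and does not exceed the cutoff (default
    36 s, the short-protocol observation window); everything else —
    including curves that plateau below 80% — is slow.
    """
    if kin.t80_s is not None and kin.t80_s <= fast_t80_cutoff_s:
        kin.population = "fast"
    else:
        kin.population = "slow"
    return kin.population


def fold_over_reference(
    target_time_s: float, reference_times_s: list[float]
) -> float:
    """Recovery time divided by the mean reference (diffusion) time."""
    if not reference_times_s:
        raise FrapError("reference time list must be non-empty")
    if target_time_s <= 0 or any(t <= 0 for t in reference_times_s):
        raise FrapError("times must be > 0")
    return float(target_time_s / np.mean(reference_times_s))


def round_half_up(value: float, decimals: int) -> float:
    """Display rounding: round half away from zero at *decimals*."""
    import decimal

    q = decimal.Decimal(10) ** -decimals
    return float(
        decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


# ---------------------------------------------------------------------------
# Curve ensembles
# ---------------------------------------------------------------------------


def _shared_time_base(
    curves: list[NormalizedFrapCurve],
) -> tuple[np.ndarray, np.ndarray, int]:
    """Stack curves on the first curve's time base (linear resampling)."""
    if not curves:
        raise FrapError("need at least one curve")
    base = curves[0]
    values = np.empty((len(curves), len(base.times_s)))
    for i, c in enumerate(curves):
        if len(c.times_s) == len(base.times_s) and np.allclose(
            c.times_s, base.times_s
        ):
            values[i] = c.values
        else:
            values[i] = np.interp(base.times_s, c.times_s, c.values)
    return base.times_s, values, base.n_pre


def mean_curve_with_sd(
    curves: list[NormalizedFrapCurve],
) -> tuple[NormalizedFrapCurve, np.ndarray | None]:
    """Pointwise mean curve and sample SD (None for a single curve)."""
    times, values, n_pre = _shared_time_base(curves)
    mean = NormalizedFrapCurve(
        times_s=times, values=values.mean(axis=0), n_pre=n_pre
    )
    sd = values.std(axis=0, ddof=1) if len(curves) > 1 else None
    return mean, sd


def pointwise_ttest_curve(
    group_a: list[NormalizedFrapCurve], group_b: list[NormalizedFrapCurve]
) -> tuple[np.ndarray, np.ndarray]:
    """Welch two-sided two-sample t-test at each time point.

    Returns (times, p-values).  Frames where both groups have zero
    variance and equal means get p = 1.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise FrapError("each group needs at least 2 curves")
    times, va, _ = _shared_time_base(group_a)
    _, vb, _ = _shared_time_base(group_b + group_a[:1])  # reuse base check
    vb = np.empty((len(group_b), len(times)))
    for i, c in enumerate(group_b):
        vb[i] = np.interp(times, c.times_s, c.values)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(va, vb, axis=0, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        same = np.isclose(va.mean(axis=0), vb.mean(axis=0))
        p[degenerate & same] = 1.0
        p[degenerate & ~same] = 0.0
    return times, p
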