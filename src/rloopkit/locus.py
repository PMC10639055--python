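"""Telomere scoring, line profiles and single-locus intensity tracking.

Telomeres are segmented in 3D on the marker channel with the wavelet
detector; each segmented object's mean sensor intensity is compared to
the diffuse nucleoplasmic sensor background of the same cell, and the
fraction of telomeres above background is reported.

The locus tracker follows a single diffraction-limited marker spot
across frames by its background-subtracted intensity-weighted centroid
(center of intensity) and reads out the sensor intensity at the tracked
position, with a local-shell background that absorbs slow acquisition
photobleaching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .detect import WaveletSettings, labeled_components
from .stacks import ImageStack, PolygonRoi


class LocusError(ValueError):
    pass


@dataclass
class SegmentedObject:
    """A segmented 3D marker focus with its sensor readout."""

    id: int
    voxels: np.ndarray  # (n, 3) array of (z, y, x) indices
    centroid: tuple[float, float, float]  # (x, y, z)
    mean_marker_intensity: float
    mean_sensor_intensity: float | None = None
    background_sensor_intensity: float | None = None
    above_background: bool | None = None


@dataclass
class LocusTrack:
    times_s: np.ndarray
    positions: np.ndarray  # (n, 3) of (x, y, z)
    sensor_series: np.ndarray
    marker_series: np.ndarray
    lost_frames: list[int]


# ---------------------------------------------------------------------------
# Telomere segmentation and above-background scoring
# ---------------------------------------------------------------------------


def segment_marker_foci(
    marker: ImageStack, settings: WaveletSettings | None = None
) -> list[SegmentedObject]:
    """Segment marker (e.g. telomere) foci in 3D; keeps voxel sets."""
    settings = settings or WaveletSettings()
    volume = marker.squeezed_spatial().astype(float)
    labels, kept = labeled_components(marker, settings)
    objects: list[SegmentedObject] = []
    for oid, lab in enumerate(kept, start=1):
        zz, yy, xx = np.nonzero(labels == lab)
        vals = volume[zz, yy, xx]
        total = vals.sum()
        w = vals / total if total > 0 else np.full(len(vals), 1.0 / len(vals))
        objects.append(
            SegmentedObject(
                id=oid,
                voxels=np.column_stack([zz, yy, xx]),
                centroid=(
                    float((xx * w).sum()),
                    float((yy * w).sum()),
                    float((zz * w).sum()),
                ),
                mean_marker_intensity=float(vals.mean()),
            )
        )
    return objects


def fraction_above_background(
    objects: list[SegmentedObject],
    sensor: ImageStack,
    background_roi: PolygonRoi,
    k_sd: float = 2.0,
) -> float | None:
    """Fraction of objects whose mean sensor intensity exceeds the
    cell's diffuse background by *k_sd* standard deviations.

    Annotates every object (mean sensor intensity, background, flag).
    Returns ``None`` for an empty object list.
    """
    volume = sensor.squeezed_spatial().astype(float)
    nz = volume.shape[0]
    bg_mask = background_roi.mask(volume.shape[1:])
    z_sel = [z for z in range(nz) if background_roi.contains_z(z, nz)]
    bg_vox = volume[z_sel][:, bg_mask]
    bg_mean = float(bg_vox.mean())
    bg_sd = float(bg_vox.std(ddof=1))
    threshold = bg_mean + k_sd * bg_sd
    n_above = 0
    for obj in objects:
        zz, yy, xx = obj.voxels.T
        obj.mean_sensor_intensity = float(volume[zz, yy, xx].mean())
        obj.background_sensor_intensity = bg_mean
        obj.above_background = bool(obj.mean_sensor_intensity > threshold)
        n_above += obj.above_background
    if not objects:
        return None
    return n_above / len(objects)


# ---------------------------------------------------------------------------
# Line profiles
# ---------------------------------------------------------------------------


def line_profile(
    stack: ImageStack,
    p0: tuple[float, float],
    p1: tuple[float, float],
    channels: list[int] | None = None,
) -> np.ndarray:
    """Bilinear line profile at unit-pixel spacing, per channel.

    Works on a 2D image or the central slice of a z-stack; returns an
    array of shape (n_channels, n_samples).
    """
    x0, y0 = p0
    x1, y1 = p1
    length = float(np.hypot(x1 - x0, y1 - y0))
    if length == 0:
        raise LocusError("zero-length line segment")
    n = int(np.floor(length)) + 1
    ts = np.linspace(0.0, 1.0, n)
    xs = x0 + ts * (x1 - x0)
    ys = y0 + ts * (y1 - y0)

    if stack.has_axis("c"):
        n_ch = stack.extent("c")
        chans = channels if channels is not None else list(range(n_ch))
        planes = [_central_plane(stack.take("c", c)) for c in chans]
    else:
        planes = [_central_plane(stack)]
    return np.stack([_bilinear(pl, xs, ys) for pl in planes])


def _central_plane(stack: ImageStack) -> np.ndarray:
    data = stack.squeezed_spatial().astype(float)
    return data[data.shape[0] // 2]


def _bilinear(plane: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    ny, nx = plane.shape
    x0 = np.clip(np.floor(xs).astype(int), 0, nx - 1)
    y0 = np.clip(np.floor(ys).astype(int), 0, ny - 1)
    x1 = np.clip(x0 + 1, 0, nx - 1)
    y1 = np.clip(y0 + 1, 0, ny - 1)
    fx = np.clip(xs - x0, 0.0, 1.0)
    fy = np.clip(ys - y0, 0.0, 1.0)
    top = plane[y0, x0] * (1 - fx) + plane[y0, x1] * fx
    bot = plane[y1, x0] * (1 - fx) + plane[y1, x1] * fx
    return top * (1 - fy) + bot * fy


# ---------------------------------------------------------------------------
# Single-locus tracking
# ---------------------------------------------------------------------------


def track_locus(
    timelapse: ImageStack,
    marker_channel: int = 1,
    sensor_channel: int = 0,
    init_xy: tuple[float, float] | None = None,
    search_radius_px: int = 5,
    measure_radius_px: int = 3,
) -> LocusTrack:
    """Track one locus by the marker's center of intensity per frame.

    Per frame, the marker's background-subtracted intensity-weighted
    3D centroid is computed in a search box around the previous
    position.  The sensor series is the mean sensor intensity in a
    sphere of *measure_radius_px* at the tracked position minus the
    median of a surrounding 2–4 px shell.  If the marker vanishes in
    the box, the position is carried forward and the frame flagged.
    """
    if "t" not in timelapse.axes or "c" not in timelapse.axes:
        raise LocusError("expected a (t, c, z, y, x) time-lapse")
    n_frames = timelapse.extent("t")
    shells = _sphere_offsets(measure_radius_px, measure_radius_px + 4)

    positions = np.empty((n_frames, 3))
    sensor_series = np.empty(n_frames)
    marker_series = np.empty(n_frames)
    lost: list[int] = []

    first = timelapse.take("t", 0).take("c", marker_channel).squeezed_spatial()
    nz, ny, nx = first.shape
    if init_xy is None:
        zc, yc, xc = np.unravel_index(np.argmax(first), first.shape)
        prev = np.array([float(xc), float(yc), float(zc)])
    else:
        prev = np.array([init_xy[0], init_xy[1], nz / 2.0])

    for f in range(n_frames):
        frame = timelapse.take("t", f)
        marker = frame.take("c", marker_channel).squeezed_spatial().astype(float)
        sensor = frame.take("c", sensor_channel).squeezed_spatial().astype(float)

        x0 = int(np.clip(round(prev[0]) - search_radius_px, 0, nx - 1))
        x1 = int(np.clip(round(prev[0]) + search_radius_px + 1, 1, nx))
        y0 = int(np.clip(round(prev[1]) - search_radius_px, 0, ny - 1))
        y1 = int(np.clip(round(prev[1]) + search_radius_px + 1, 1, ny))
        box = marker[:, y0:y1, x0:x1]
        local_bg = np.median(box)
        # robust noise cutoff: clipped shot noise would otherwise pull
        # the centroid toward the box center
        noise_sd = np.median(np.abs(box - local_bg)) / 0.6745
        weights = np.clip(box - (local_bg + 3.0 * noise_sd), 0.0, None)
        total = weights.sum()
        if total <= 0:
            lost.append(f)
            pos = prev
        else:
            zz, yy, xx = np.mgrid[0:nz, y0:y1, x0:x1]
            pos = np.array(
                [
                    (xx * weights).sum() / total,
                    (yy * weights).sum() / total,
                    (zz * weights).sum() / total,
                ]
            )
        positions[f] = pos
        prev = pos

        marker_series[f] = _sphere_mean(marker, pos, measure_radius_px)
        core = _sphere_mean(sensor, pos, measure_radius_px)
        shell_vals = _shell_values(sensor, pos, shells)
        sensor_series[f] = core - float(np.median(shell_vals))

    return LocusTrack(
        times_s=timelapse.frame_times_s(),
        positions=positions,
        sensor_series=sensor_series,
        marker_series=marker_series,
        lost_frames=lost,
    )


def _sphere_mean(volume: np.ndarray, pos_xyz: np.ndarray, radius: float) -> float:
    nz, ny, nx = volume.shape
    x, y, z = pos_xyz
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]
    mask = (xx - x) ** 2 + (yy - y) ** 2 + (zz - z) ** 2 <= radius**2
    if not mask.any():
        return float("nan")
    return float(volume[mask].mean())


def _sphere_offsets(r_in: float, r_out: float) -> tuple[float, float]:
    return (r_in + 2.0, min(r_out, r_in + 4.0))


def _shell_values(
    volume: np.ndarray, pos_xyz: np.ndarray, shell: tuple[float, float]
) -> np.ndarray:
    nz, ny, nx = volume.shape
    x, y, z = pos_xyz
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]
    d2 = (xx - x) ** 2 + (yy - y) ** 2 + (zz - z) ** 2
    mask = (d2 > shell[0] ** 2) & (d2 <= shell[1] ** 2)
    if not mask.any():
        return np.array([0.0])
    return volume[mask]


# ---------------------------------------------------------------------------
# Burst-cycle detection and treatment response
# ---------------------------------------------------------------------------


def detect_fluctuation_cycles(
    track: LocusTrack,
    smooth_window: int = 3,
    min_prominence: float = 1.0,
) -> tuple[np.ndarray, float | None]:
    """Peak times of the sensor series and the median inter-peak period.

    Centered moving-average smoothing; peaks must have prominence of at
    least ``min_prominence`` times the smoothed series' SD.  Fewer than
    two peaks gives period ``None``.
    """
    v = np.asarray(track.sensor_series, dtype=float)
    if len(v) < 3:
        raise LocusError("need at least 3 frames")
    if smooth_window > 1:
        from scipy.ndimage import uniform_filter1d

        v = uniform_filter1d(v, smooth_window, mode="nearest")
    sd = v.std()
    if sd == 0:
        return np.array([]), None
    peaks, _ = signal.find_peaks(v, prominence=min_prominence * sd)
    peak_times = track.times_s[peaks]
    if len(peaks) < 2:
        return peak_times, None
    return peak_times, float(np.median(np.diff(peak_times)))


def treatment_response_test(
    pre_values: np.ndarray, post_series: np.ndarray
) -> np.ndarray:
    """Welch two-sided t-test of pre-treatment values against each post
    time point.

    *pre_values* has one entry per cell; *post_series* is (n_cells,
    n_timepoints).  Returns a p-value per post time point.
    """
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_series, dtype=float)
    if post.ndim == 1:
        post = post[:, np.newaxis]
    if len(pre) < 2 or post.shape[0] < 2:
        raise LocusError(
            "need at least 2 cells per comparison; for a single cell use "
            "a paired design instead"
        )
    res = stats.ttest_ind(
        pre[:, np.newaxis], post, axis=0, equal_var=False
    )
    p = np.asarray(res.pvalue, dtype=float)
    p[np.isnan(p)] = 1.0
    return p
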