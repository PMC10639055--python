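"""Synthetic fluorescence-microscopy data with known ground truth.

Every analysis stage in this package is exercised against scenes,
FRAP time-lapses and locus time series produced here, so that expected
values come from the generator's ground-truth record and never from the
rendered image itself.

What is emulated
----------------
* nuclei with a diffuse sensor background (elevated inside nucleolar
  subregions) and PSF-blurred foci of heterogeneous intensity;
* a telomere-marker channel plus a sensor channel where a chosen subset
  of telomeres carries sensor accumulation;
* a locus-marker channel with burst-like sensor fluctuations and an
  optional transcription-inhibitor (DRB-style) signal decay;
* FRAP time-lapses with multi-exponential recovery, per-frame
  acquisition photobleaching and Poisson + Gaussian camera noise.

The camera noise chain is fixed as Poisson (photon shot noise) ->
additive Gaussian read noise -> gain -> integer quantisation, so
variance-based assertions have closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .frap import FrapExperiment
from .stacks import CircleRoi, ImageStack, PolygonRoi, ellipse_roi, rectangle_roi


class ConfigurationError(ValueError):
    """Raised for impossible or inconsistent simulation settings."""


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------


@dataclass
class FocusTruth:
    centroid: tuple[float, float, float]  # (x, y, z) voxel coordinates
    total_intensity: float  # photons
    sigma_vox: tuple[float, float, float]  # (x, y, z)
    sensor_positive: bool | None = None


@dataclass
class SyntheticGroundTruth:
    """Record of everything the generator placed into a simulation."""

    foci: list[FocusTruth] = field(default_factory=list)
    true_recovery: np.ndarray | None = None  # noise-free normalized R(t)
    recovery_times_s: np.ndarray | None = None
    plateau: float | None = None
    burst_times: list[tuple[float, float]] = field(default_factory=list)
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Camera noise chain
# ---------------------------------------------------------------------------


def apply_camera(
    photons: np.ndarray,
    rng: np.random.Generator,
    read_noise_sd: float = 2.0,
    gain: float = 1.0,
    poisson_noise: bool = True,
    bit_depth: int = 16,
) -> np.ndarray:
    """Poisson -> Gaussian read -> gain -> quantize, returning uint16."""
    if poisson_noise:
        counts = rng.poisson(photons).astype(float)
    else:
        counts = np.asarray(photons, dtype=float)
    if read_noise_sd > 0:
        counts = counts + rng.normal(0.0, read_noise_sd, size=counts.shape)
    counts = counts * gain
    limit = 2**bit_depth - 1
    return np.clip(np.rint(counts), 0, limit).astype(np.uint16)


def _gaussian_blob(
    shape_zyx: tuple[int, int, int],
    center_xyz: tuple[float, float, float],
    sigma_xyz: tuple[float, float, float],
    total_photons: float,
) -> np.ndarray:
    """Render an anisotropic Gaussian focus over a (z, y, x) grid.

    Evaluated only inside a +-4 sigma bounding box for speed.
    """
    nz, ny, nx = shape_zyx
    cx, cy, cz = center_xyz
    sx, sy, sz = sigma_xyz
    out = np.zeros(shape_zyx)
    x0, x1 = max(0, int(cx - 4 * sx)), min(nx, int(cx + 4 * sx) + 2)
    y0, y1 = max(0, int(cy - 4 * sy)), min(ny, int(cy + 4 * sy) + 2)
    z0, z1 = max(0, int(cz - 4 * sz)), min(nz, int(cz + 4 * sz) + 2)
    z, y, x = np.mgrid[z0:z1, y0:y1, x0:x1]
    peak = total_photons / ((2 * math.pi) ** 1.5 * sx * sy * sz)
    out[z0:z1, y0:y1, x0:x1] = peak * np.exp(
        -0.5 * (((x - cx) / sx) ** 2 + ((y - cy) / sy) ** 2 + ((z - cz) / sz) ** 2)
    )
    return out


# ---------------------------------------------------------------------------
# Nuclear scene
# ---------------------------------------------------------------------------


@dataclass
class SceneConfig:
    """Conditions for a synthetic nuclear scene.

    Defaults are a scaled-down spinning-disk z-stack: a 14-slice,
    128 x 128 field with a 0.16 um pixel and 0.32 um z-step, diffuse
    nuclear sensor background of 100 photons, and bright foci whose
    peak signal-to-noise against the shot noise of the diffuse level
    is well above 10.
    """

    image_shape: tuple[int, int, int] = (14, 128, 128)  # (z, y, x)
    n_foci: int = 20
    focus_intensity_range: tuple[float, float] = (1500.0, 4000.0)  # photons, total
    psf_sigma_um: tuple[float, float] = (0.11, 0.3)  # (lateral, axial)
    pixel_size_um: float = 0.16
    z_step_um: float = 0.32
    nucleus: PolygonRoi | None = None  # default: centred ellipse
    nucleolus_regions: list[PolygonRoi] = field(default_factory=list)
    diffuse_level: float = 100.0  # photons, nucleoplasm
    nucleolus_level: float = 150.0  # photons, inside nucleolar regions
    background_level: float = 10.0  # photons, extranuclear
    read_noise_sd: float = 2.0  # counts
    gain: float = 1.0  # counts / photon
    poisson_noise: bool = True
    min_separation_vox: float = 7.0
    placement_margin_px: float = 10.0
    edge_softness_px: float = 1.0  # optical blur of the nuclear envelope
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_foci < 0:
            raise ConfigurationError("n_foci must be >= 0")
        if min(self.psf_sigma_um) <= 0:
            raise ConfigurationError("psf widths must be > 0")
        for name in ("diffuse_level", "background_level", "nucleolus_level"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.nucleus is None:
            _, ny, nx = self.image_shape
            self.nucleus = ellipse_roi(
                nx / 2, ny / 2, 0.42 * nx, 0.36 * ny, label="nucleus"
            )

    @property
    def sigma_vox(self) -> tuple[float, float, float]:
        lat = self.psf_sigma_um[0] / self.pixel_size_um
        ax = self.psf_sigma_um[1] / self.z_step_um
        return (lat, lat, ax)


def _place_foci(cfg: SceneConfig, rng: np.random.Generator) -> list[tuple[float, float, float]]:
    nz, ny, nx = cfg.image_shape
    poly = cfg.nucleus.polygon.buffer(-cfg.placement_margin_px)
    if poly.is_empty:
        raise ConfigurationError("nucleus too small for focus placement")
    minx, miny, maxx, maxy = poly.bounds
    z_lo, z_hi = 2.0, nz - 3.0
    if z_hi <= z_lo:
        raise ConfigurationError("too few z slices for focus placement")
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    import shapely

    while len(placed) < cfg.n_foci:
        attempts += 1
        if attempts > 20000:
            raise ConfigurationError(
                "focus placement failed: nucleus too small for "
                f"{cfg.n_foci} foci at separation {cfg.min_separation_vox}"
            )
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if not shapely.contains_xy(poly, x, y):
            continue
        z = rng.uniform(z_lo, z_hi)
        ok = all(
            (x - px) ** 2 + (y - py) ** 2 + (z - pz) ** 2
            >= cfg.min_separation_vox**2
            for px, py, pz in placed
        )
        if ok:
            placed.append((x, y, z))
    return placed


def scene_template(cfg: SceneConfig) -> np.ndarray:
    """Deterministic photon-rate template without foci: extranuclear
    background, diffuse nuclear level, elevated nucleolar subregions.

    The nuclear envelope is softened with a Gaussian of
    ``edge_softness_px`` — confocal images show a blurred, not a hard,
    boundary between nucleoplasm and surround.
    """
    nz, ny, nx = cfg.image_shape
    nuc_mask = cfg.nucleus.mask((ny, nx))
    plane = np.where(nuc_mask, cfg.diffuse_level, cfg.background_level).astype(float)
    for region in cfg.nucleolus_regions:
        plane = np.where(region.mask((ny, nx)), cfg.nucleolus_level, plane)
    if cfg.edge_softness_px > 0:
        from scipy import ndimage

        plane = ndimage.gaussian_filter(plane, cfg.edge_softness_px)
    return np.broadcast_to(plane, (nz, ny, nx)).copy()


def simulate_nucleus_scene(
    cfg: SceneConfig,
) -> tuple[ImageStack, SyntheticGroundTruth]:
    """Render a 16-bit (z, y, x) scene and its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    template = scene_template(cfg)
    truth = SyntheticGroundTruth(params={"type": "scene", "seed": cfg.seed})
    sig = cfg.sigma_vox
    for center in _place_foci(cfg, rng):
        total = rng.uniform(*cfg.focus_intensity_range)
        template += _gaussian_blob(cfg.image_shape, center, (sig[0], sig[1], sig[2]), total)
        truth.foci.append(
            FocusTruth(centroid=center, total_intensity=float(total), sigma_vox=sig)
        )
    data = apply_camera(
        template, rng, cfg.read_noise_sd, cfg.gain, cfg.poisson_noise
    )
    stack = ImageStack(
        data=data,
        axes="zyx",
        voxel_size_um={
            "z": cfg.z_step_um,
            "y": cfg.pixel_size_um,
            "x": cfg.pixel_size_um,
        },
    )
    return stack, truth


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------


@dataclass
class FrapSimConfig:
    """Conditions for a simulated FRAP experiment.

    Defaults follow the short acquisition protocol: 5 pre-bleach and
    120 post-bleach frames at 0.3 s intervals, a 25-pixel bleach spot,
    and a mild per-frame acquisition photobleach.  ``fractions`` lists
    ``(amplitude, rate_per_s)`` recovery components; together with
    ``immobile_fraction`` the amplitudes must not exceed 1.
    """

    fractions: list[tuple[float, float]] = field(
        default_factory=lambda: [(1.0, math.log(2) / 3.0)]
    )
    immobile_fraction: float = 0.0
    bleach_depth: float = 0.9
    n_pre: int = 5
    n_post: int = 120
    dt_s: float = 0.3
    acquisition_bleach_rate: float = 0.001  # per-frame multiplicative decay
    roi_level_photons: float = 400.0  # pre-bleach bleach-ROI mean, above bg
    reference_level_photons: float = 400.0
    background_photons: float = 20.0
    roi_n_px: int = 490  # ~25-px-diameter disc
    reference_n_px: int = 5000
    background_n_px: int = 2000
    read_noise_sd: float = 2.0
    gain: float = 1.0
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        amp = sum(f for f, _ in self.fractions)
        if amp + self.immobile_fraction > 1.0 + 1e-12:
            raise ConfigurationError(
                "sum of mobile fractions plus immobile_fraction exceeds 1"
            )
        if any(k <= 0 for _, k in self.fractions):
            raise ConfigurationError("recovery rates must be > 0")
        if any(f <= 0 for f, _ in self.fractions):
            raise ConfigurationError("component amplitudes must be > 0")
        if not (0 <= self.immobile_fraction < 1):
            raise ConfigurationError("immobile_fraction must be in [0, 1)")
        if not (0 < self.bleach_depth <= 1):
            raise ConfigurationError("bleach_depth must be in (0, 1]")
        if self.n_pre < 1 or self.n_post < 1:
            raise ConfigurationError("need n_pre >= 1 and n_post >= 1")


def true_recovery(cfg: FrapSimConfig, t_s: np.ndarray) -> np.ndarray:
    """Noise-free normalized recovery: R(0) = 0 and
    R(inf) = 1 - immobile/(mobile + immobile)."""
    t_s = np.asarray(t_s, dtype=float)
    s = sum(f for f, _ in cfg.fractions) + cfg.immobile_fraction
    r = np.zeros_like(t_s)
    for f, k in cfg.fractions:
        r += f * (1.0 - np.exp(-k * t_s))
    return r / s


def _mean_with_noise(
    lam: np.ndarray,
    n_px: int,
    rng: np.random.Generator,
    cfg: FrapSimConfig,
) -> np.ndarray:
    """ROI-mean series: normal approximation of the averaged noise chain."""
    if not cfg.noise:
        return cfg.gain * lam
    sd = np.sqrt((lam + cfg.read_noise_sd**2) / n_px)
    return cfg.gain * (lam + rng.normal(0.0, 1.0, size=lam.shape) * sd)


def simulate_frap_experiment(
    cfg: FrapSimConfig,
) -> tuple[FrapExperiment, SyntheticGroundTruth]:
    """Generate the raw measurement triple for one FRAP experiment.

    The ROI, background and reference series are constructed
    consistently, so double normalization recovers the ground-truth
    recovery exactly in the noise-free case (the reference series
    carries the same per-frame acquisition decay as the bleach ROI).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_pre + cfg.n_post
    frames = np.arange(n)
    times = frames * cfg.dt_s
    decay = (1.0 - cfg.acquisition_bleach_rate) ** frames

    post_t = (np.arange(cfg.n_post)) * cfg.dt_s
    r_true = true_recovery(cfg, post_t)
    floor = 1.0 - cfg.bleach_depth
    recovery_factor = np.ones(n)
    recovery_factor[cfg.n_pre:] = floor + (1.0 - floor) * r_true

    lam_roi = cfg.background_photons + cfg.roi_level_photons * recovery_factor * decay
    lam_ref = cfg.background_photons + cfg.reference_level_photons * decay
    lam_bg = np.full(n, cfg.background_photons)

    exp = FrapExperiment(
        times_s=times,
        roi_series=_mean_with_noise(lam_roi, cfg.roi_n_px, rng, cfg),
        background_series=_mean_with_noise(lam_bg, cfg.background_n_px, rng, cfg),
        reference_series=_mean_with_noise(lam_ref, cfg.reference_n_px, rng, cfg),
        n_pre=cfg.n_pre,
        bleach_roi=CircleRoi(center=(0.0, 0.0), diameter_px=25, label="bleach"),
    )
    s = sum(f for f, _ in cfg.fractions) + cfg.immobile_fraction
    truth = SyntheticGroundTruth(
        true_recovery=r_true,
        recovery_times_s=post_t,
        plateau=float(1.0 - cfg.immobile_fraction / s),
        params={"type": "frap", "seed": cfg.seed},
    )
    return exp, truth


def simulate_frap_movie(
    cfg: FrapSimConfig,
    shape_yx: tuple[int, int] = (96, 96),
) -> tuple[ImageStack, dict, SyntheticGroundTruth]:
    """Image-domain FRAP time-lapse plus the three measurement ROIs.

    A single-plane movie: an elliptical cell over a dark surround, a
    central 25-px bleach circle, per-frame acquisition decay, and the
    configured recovery inside the bleach spot.
    """
    rng = np.random.default_rng(cfg.seed)
    ny, nx = shape_yx
    n = cfg.n_pre + cfg.n_post
    frames = np.arange(n)
    decay = (1.0 - cfg.acquisition_bleach_rate) ** frames
    post_t = np.arange(cfg.n_post) * cfg.dt_s
    r_true = true_recovery(cfg, post_t)
    floor = 1.0 - cfg.bleach_depth
    recovery_factor = np.ones(n)
    recovery_factor[cfg.n_pre:] = floor + (1.0 - floor) * r_true

    cell = ellipse_roi(nx * 0.42, ny * 0.5, nx * 0.34, ny * 0.4, label="cell")
    bleach = CircleRoi(center=(nx * 0.42, ny * 0.5), diameter_px=25, label="bleach")
    background = rectangle_roi(nx - 14.0, 2.0, nx - 2.0, ny - 3.0, label="background")

    cell_mask = cell.mask(shape_yx)
    bleach_mask = bleach.mask(shape_yx)
    movie = np.empty((n, ny, nx), dtype=np.uint16)
    for f in range(n):
        lam = np.full(shape_yx, cfg.background_photons)
        lam[cell_mask] += cfg.reference_level_photons * decay[f]
        lam[bleach_mask & cell_mask] = (
            cfg.background_photons
            + cfg.roi_level_photons * recovery_factor[f] * decay[f]
        )
        movie[f] = apply_camera(
            lam, rng, cfg.read_noise_sd, cfg.gain, poisson_noise=cfg.noise
        )
    stack = ImageStack(data=movie, axes="tyx", time_interval_s=cfg.dt_s)
    s = sum(f for f, _ in cfg.fractions) + cfg.immobile_fraction
    truth = SyntheticGroundTruth(
        true_recovery=r_true,
        recovery_times_s=post_t,
        plateau=float(1.0 - cfg.immobile_fraction / s),
        params={"type": "frap_movie", "seed": cfg.seed},
    )
    rois = {"cell": cell, "bleach": bleach, "background": background}
    return stack, rois, truth


# -- kinetic presets used as the two telomeric study populations ----------

#: fast telomeric population: single component reaching 80% recovery in
#: 8.1 s (k = ln5 / 8.1).
FAST_TELOMERIC = {"fractions": [(1.0, math.log(5) / 8.1)], "immobile_fraction": 0.0}

#: slow telomeric population: recovers to a plateau of 0.65 with a
#: characteristic time that approaches the plateau by ~35 s.
SLOW_TELOMERIC = {"fractions": [(0.65, 0.12)], "immobile_fraction": 0.35}


# ---------------------------------------------------------------------------
# Locus time-lapse
# ---------------------------------------------------------------------------


def burst_schedule(
    burst_period_s: float, burst_duration_s: float, total_s: float
) -> list[tuple[float, float]]:
    """On/off intervals: floor(total / period) bursts, one per period,
    phase-shifted by half a period so no burst straddles t = 0."""
    n_bursts = int(total_s // burst_period_s)
    return [
        ((i + 0.5) * burst_period_s, (i + 0.5) * burst_period_s + burst_duration_s)
        for i in range(n_bursts)
    ]


def simulate_locus_timelapse(
    burst_period_s: float = 45.0,
    burst_duration_s: float = 20.0,
    drb_time_s: float | None = None,
    n_frames: int = 75,
    dt_s: float = 8.0,
    drb_tau_s: float = 360.0,
    shape_zyx: tuple[int, int, int] = (7, 48, 48),
    marker_level: float = 3000.0,
    sensor_on_level: float = 2500.0,
    diffuse_level: float = 100.0,
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0),
    read_noise_sd: float = 2.0,
    gain: float = 1.0,
    poisson_noise: bool = True,
    seed: int = 0,
) -> tuple[ImageStack, SyntheticGroundTruth]:
    """Two-channel (t, c, z, y, x) time-lapse of a single gene locus.

    Channel 0 is the sensor, channel 1 the (static) locus marker.  The
    sensor amplitude follows square on/off bursts; after *drb_time_s*
    it decays exponentially with time constant *drb_tau_s* (default
    chosen so the signal sits at background within ~30 min).
    """
    if burst_duration_s >= burst_period_s:
        raise ConfigurationError("burst_duration_s must be < burst_period_s")
    if dt_s <= 0:
        raise ConfigurationError("dt_s must be > 0")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape_zyx
    total_s = n_frames * dt_s
    schedule = burst_schedule(burst_period_s, burst_duration_s, total_s)
    center = (nx / 2.0, ny / 2.0, nz / 2.0)
    sigma = (0.9, 0.9, 1.0)

    def schedule_amp(t: float) -> float:
        return sensor_on_level if any(a <= t < b for a, b in schedule) else 0.0

    data = np.empty((n_frames, 2, nz, ny, nx), dtype=np.uint16)
    positions = np.empty((n_frames, 3))
    for f in range(n_frames):
        t = f * dt_s
        if drb_time_s is not None and t >= drb_time_s:
            amp = schedule_amp(drb_time_s) * math.exp(-(t - drb_time_s) / drb_tau_s)
        else:
            amp = schedule_amp(t)
        pos = (
            center[0] + f * drift_px_per_frame[0],
            center[1] + f * drift_px_per_frame[1],
            center[2],
        )
        positions[f] = pos
        marker_blob = _gaussian_blob(shape_zyx, pos, sigma, marker_level)
        sensor_unit = _gaussian_blob(shape_zyx, pos, sigma, 1.0)
        sensor_lam = diffuse_level + amp * sensor_unit
        marker_lam = diffuse_level + marker_blob
        data[f, 0] = apply_camera(sensor_lam, rng, read_noise_sd, gain, poisson_noise)
        data[f, 1] = apply_camera(marker_lam, rng, read_noise_sd, gain, poisson_noise)

    stack = ImageStack(data=data, axes="tczyx", time_interval_s=dt_s)
    kept = [
        (a, b)
        for a, b in schedule
        if drb_time_s is None or a < drb_time_s
    ]
    truth = SyntheticGroundTruth(
        burst_times=kept,
        params={
            "type": "locus",
            "seed": seed,
            "center": center,
            "positions": positions,
            "drb_time_s": drb_time_s,
            "drb_tau_s": drb_tau_s,
        },
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Telomere scene: marker channel plus sensor channel
# ---------------------------------------------------------------------------


def simulate_telomere_scene(
    n_telomeres: int = 100,
    n_with_sensor: int = 32,
    sensor_contrast: float = 10.0,
    shape_zyx: tuple[int, int, int] = (14, 160, 160),
    marker_intensity: float = 3000.0,
    diffuse_level: float = 100.0,
    read_noise_sd: float = 2.0,
    gain: float = 1.0,
    poisson_noise: bool = True,
    seed: int = 0,
) -> tuple[ImageStack, ImageStack, PolygonRoi, SyntheticGroundTruth]:
    """A nucleus with *n_telomeres* marker foci of which *n_with_sensor*
    carry sensor accumulation at *sensor_contrast* times the diffuse
    background.

    Returns ``(marker_stack, sensor_stack, background_roi, truth)``;
    the background ROI is a focus-free nucleoplasmic rectangle, and
    ``truth.foci[i].sensor_positive`` flags the marked telomeres.
    """
    if not 0 <= n_with_sensor <= n_telomeres:
        raise ConfigurationError("need 0 <= n_with_sensor <= n_telomeres")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape_zyx
    nucleus = ellipse_roi(nx / 2, ny / 2, 0.44 * nx, 0.38 * ny, label="nucleus")
    bg_roi = rectangle_roi(
        nx / 2 - 9, ny / 2 - 9, nx / 2 + 9, ny / 2 + 9, label="background"
    )

    cfg = SceneConfig(
        image_shape=shape_zyx,
        n_foci=n_telomeres,
        nucleus=nucleus,
        min_separation_vox=7.0,
        seed=seed,
    )
    # dart-throwing placement, excluding the reserved background patch
    import shapely

    exclusion = shapely.box(
        nx / 2 - 13, ny / 2 - 13, nx / 2 + 13, ny / 2 + 13
    )
    positions: list[tuple[float, float, float]] = []
    poly = nucleus.polygon.buffer(-cfg.placement_margin_px)
    minx, miny, maxx, maxy = poly.bounds
    attempts = 0
    while len(positions) < n_telomeres:
        attempts += 1
        if attempts > 100000:
            raise ConfigurationError("telomere placement failed")
        x, y = rng.uniform(minx, maxx), rng.uniform(miny, maxy)
        if not shapely.contains_xy(poly, x, y) or shapely.contains_xy(exclusion, x, y):
            continue
        z = rng.uniform(2.0, nz - 3.0)
        if all(
            (x - px) ** 2 + (y - py) ** 2 + (z - pz) ** 2 >= cfg.min_separation_vox**2
            for px, py, pz in positions
        ):
            positions.append((x, y, z))

    sig = cfg.sigma_vox
    # telomere markers sit on a low, flat diffuse background; the sensor
    # channel shows the nucleus (softened envelope) like the scene model
    marker_lam = np.full(shape_zyx, 20.0)
    sensor_plane = np.where(nucleus.mask((ny, nx)), diffuse_level, 10.0).astype(float)
    from scipy import ndimage as _ndi

    sensor_plane = _ndi.gaussian_filter(sensor_plane, 1.0)
    sensor_lam = np.broadcast_to(sensor_plane, shape_zyx).copy()

    truth = SyntheticGroundTruth(params={"type": "telomeres", "seed": seed})
    marked = set(rng.choice(n_telomeres, size=n_with_sensor, replace=False).tolist())
    peak_factor = (2 * math.pi) ** 1.5 * sig[0] * sig[1] * sig[2]
    for i, pos in enumerate(positions):
        marker_lam += _gaussian_blob(shape_zyx, pos, sig, marker_intensity)
        positive = i in marked
        if positive:
            # peak sensor amplitude = contrast x diffuse background
            total = sensor_contrast * diffuse_level * peak_factor
            sensor_lam += _gaussian_blob(shape_zyx, pos, sig, total)
        truth.foci.append(
            FocusTruth(
                centroid=pos,
                total_intensity=marker_intensity,
                sigma_vox=sig,
                sensor_positive=positive,
            )
        )

    marker = ImageStack(
        data=apply_camera(marker_lam, rng, read_noise_sd, gain, poisson_noise),
        axes="zyx",
    )
    sensor = ImageStack(
        data=apply_camera(sensor_lam, rng, read_noise_sd, gain, poisson_noise),
        axes="zyx",
    )
    return marker, sensor, bg_roi, truth


# ---------------------------------------------------------------------------
# Nuclei + foci projections for per-nucleus counting
# ---------------------------------------------------------------------------


def simulate_nuclei_projection(
    foci_per_nucleus: list[int],
    shape_yx: tuple[int, int] = (192, 192),
    nucleus_radius_px: int = 36,
    focus_side_px: int = 3,
    nuclear_level: float = 1000.0,
    focus_level: float = 800.0,
    cell_background: float = 50.0,
    seed: int = 0,
) -> tuple[ImageStack, ImageStack, SyntheticGroundTruth]:
    """2D nuclear-stain and foci-stain projections with known counts.

    One round nucleus per entry of *foci_per_nucleus*; each focus is a
    ``focus_side_px`` square (area = side^2 pixels) placed inside its
    nucleus without overlap.
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape_yx
    n_nuc = len(foci_per_nucleus)
    yy, xx = np.mgrid[0:ny, 0:nx]
    nuclear = np.zeros(shape_yx)
    foci = np.zeros(shape_yx)
    centers = []
    spacing = nx / (n_nuc + 1)
    # keep nuclei disjoint regardless of how many are requested
    nucleus_radius_px = int(min(nucleus_radius_px, spacing / 2 - 4))
    if nucleus_radius_px < 10:
        raise ConfigurationError("too many nuclei for the image width")
    for i in range(n_nuc):
        cx, cy = spacing * (i + 1), ny / 2
        centers.append((cx, cy))
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= nucleus_radius_px**2
        nuclear[disk] = nuclear_level
        foci[disk] = cell_background
    truth = SyntheticGroundTruth(params={"type": "projection", "seed": seed})
    half = focus_side_px // 2
    for (cx, cy), n_foci in zip(centers, foci_per_nucleus):
        placed: list[tuple[int, int]] = []
        while len(placed) < n_foci:
            r = rng.uniform(0, nucleus_radius_px - 6)
            th = rng.uniform(0, 2 * math.pi)
            fx = int(cx + r * math.cos(th))
            fy = int(cy + r * math.sin(th))
            if all(abs(fx - px) + abs(fy - py) > 2 * focus_side_px for px, py in placed):
                placed.append((fx, fy))
                foci[fy - half : fy - half + focus_side_px,
                     fx - half : fx - half + focus_side_px] += focus_level
                truth.foci.append(
                    FocusTruth(
                        centroid=(float(fx), float(fy), 0.0),
                        total_intensity=focus_level * focus_side_px**2,
                        sigma_vox=(0.0, 0.0, 0.0),
                    )
                )
    nuc_stack = ImageStack(data=np.rint(nuclear).astype(np.uint16), axes="yx")
    foci_stack = ImageStack(data=np.rint(foci).astype(np.uint16), axes="yx")
    return nuc_stack, foci_stack, truth
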