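"""3D foci detection by per-scale thresholding of the à-trous transform.

The detector reproduces a multiscale "bright spots over dark background"
pipeline: each z-slice is decomposed into wavelet detail planes, each
enabled scale is thresholded with a robust (MAD-based) per-plane
threshold scaled by a sensitivity value, and a voxel is retained only if
it is supported at every enabled scale.  Retained voxels are grouped
into 26-connected 3D components, size-filtered, and optionally
restricted to a nuclear polygon by centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .stacks import ImageStack, PolygonRoi
from .wavelets import atrous_decompose, atrous_decompose_3d, detail_threshold

STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class WaveletSettings:
    """Detector settings.

    ``sensitivity_per_scale`` maps wavelet scale to a positive
    sensitivity; scales absent from the map are disabled.  Defaults
    follow the single-pixel scale disabled, scale 2 (≈3 px) at 60 and
    scale 3 (≈7 px) at 130, with 3D component sizes restricted to
    2–50 voxels and 2D per-slice wavelets.
    """

    sensitivity_per_scale: dict[int, float] = field(
        default_factory=lambda: {2: 60.0, 3: 130.0}
    )
    min_size_vox: int = 2
    max_size_vox: int = 50
    force_2d: bool = True
    noise_floor_frac: float = 0.1
    exclude_border: bool = False

    def __post_init__(self) -> None:
        if not self.sensitivity_per_scale:
            raise ValueError("at least one scale must be enabled")
        for s, sens in self.sensitivity_per_scale.items():
            if s < 1:
                raise ValueError(f"invalid scale {s}")
            if sens <= 0:
                raise ValueError(f"sensitivity for scale {s} must be > 0")
        if not (1 <= self.min_size_vox <= self.max_size_vox):
            raise ValueError("need 1 <= min_size_vox <= max_size_vox")

    @property
    def enabled_scales(self) -> list[int]:
        return sorted(self.sensitivity_per_scale)


@dataclass
class Spot:
    """A detected 3D focus."""

    centroid: tuple[float, float, float]  # (x, y, z), intensity weighted
    n_voxels: int
    total_intensity: float
    mean_intensity: float
    scales: frozenset[int]
    inside_nucleus: bool | None = None


def mean_of_channels(stack: ImageStack) -> ImageStack:
    """Arithmetic mean over the channel axis, in real values."""
    i = stack.axis_index("c")
    data = stack.data.astype(float).mean(axis=i)
    return ImageStack(
        data=data,
        axes=stack.axes.replace("c", ""),
        voxel_size_um=stack.voxel_size_um,
        time_interval_s=stack.time_interval_s,
        bit_depth=stack.bit_depth,
    )


def threshold_details(
    details: list[np.ndarray], settings: WaveletSettings
) -> dict[int, np.ndarray]:
    """Binary mask per enabled scale: ``detail > tau_scale``."""
    masks: dict[int, np.ndarray] = {}
    for scale in settings.enabled_scales:
        if scale > len(details):
            raise ValueError(
                f"scale {scale} enabled but only {len(details)} detail planes given"
            )
        d = details[scale - 1]
        tau = detail_threshold(
            d, settings.sensitivity_per_scale[scale], settings.noise_floor_frac
        )
        masks[scale] = d > tau
    return masks


def _support_mask(volume: np.ndarray, settings: WaveletSettings) -> np.ndarray:
    """Voxels supported at every enabled scale (intersection).

    Support additionally requires the voxel to sit above the residual
    smooth plane (the local background estimate): a retained voxel must
    itself be locally bright, not merely adjacent to bright structure.
    This keeps an isolated hot pixel a one-voxel component, which the
    minimum-size filter then removes.
    """
    n_scales = max(settings.enabled_scales)
    if settings.force_2d:
        mask = np.empty(volume.shape, dtype=bool)
        for z in range(volume.shape[0]):
            details, smooth = atrous_decompose(volume[z], n_scales)
            per_scale = threshold_details(details, settings)
            combined = np.logical_and.reduce(list(per_scale.values()))
            mask[z] = combined & (volume[z] > smooth)
        return mask
    details, smooth = atrous_decompose_3d(volume, n_scales)
    per_scale = threshold_details(details, settings)
    return np.logical_and.reduce(list(per_scale.values())) & (volume > smooth)


def detect_spots(
    stack: ImageStack,
    settings: WaveletSettings | None = None,
    nucleus: PolygonRoi | None = None,
) -> list[Spot]:
    """Detect 3D foci in a single-channel stack.

    Apply :func:`mean_of_channels` first for multi-channel input.
    Components outside ``[min_size_vox, max_size_vox]`` are discarded;
    when *nucleus* is given, spots whose centroid lies outside the
    polygon in x–y or outside its z range are removed.
    """
    settings = settings or WaveletSettings()
    volume = stack.squeezed_spatial().astype(float)
    if nucleus is not None:
        nucleus.validate_against(stack)

    mask = _support_mask(volume, settings)
    labels, n_labels = ndimage.label(mask, structure=STRUCT_26)
    if n_labels == 0:
        return []

    nz, ny, nx = volume.shape
    spots: list[Spot] = []
    objects = ndimage.find_objects(labels)
    for lab, slc in enumerate(objects, start=1):
        comp = labels[slc] == lab
        n_vox = int(comp.sum())
        if not (settings.min_size_vox <= n_vox <= settings.max_size_vox):
            continue
        zz, yy, xx = np.nonzero(comp)
        zz = zz + slc[0].start
        yy = yy + slc[1].start
        xx = xx + slc[2].start
        if settings.exclude_border and (
            zz.min() == 0
            or yy.min() == 0
            or xx.min() == 0
            or zz.max() == nz - 1
            or yy.max() == ny - 1
            or xx.max() == nx - 1
        ):
            continue
        vals = volume[zz, yy, xx]
        total = float(vals.sum())
        if total > 0:
            cx = float((xx * vals).sum() / total)
            cy = float((yy * vals).sum() / total)
            cz = float((zz * vals).sum() / total)
        else:  # degenerate: fall back to geometric centroid
            cx, cy, cz = float(xx.mean()), float(yy.mean()), float(zz.mean())
        inside: bool | None = None
        if nucleus is not None:
            inside = nucleus.contains_point(cx, cy) and nucleus.contains_z(
                int(round(cz)), n_slices=nz
            )
            if not inside:
                continue
        spots.append(
            Spot(
                centroid=(cx, cy, cz),
                n_voxels=n_vox,
                total_intensity=total,
                mean_intensity=total / n_vox,
                scales=frozenset(settings.enabled_scales),
                inside_nucleus=inside,
            )
        )
    return spots


def labeled_components(
    stack: ImageStack, settings: WaveletSettings | None = None
) -> tuple[np.ndarray, list[int]]:
    """Size-filtered 26-connected component labelling of the support mask.

    Returns ``(labels, kept_label_ids)``; used by the telomere
    segmentation, which needs the voxel sets and not only centroids.
    """
    settings = settings or WaveletSettings()
    volume = stack.squeezed_spatial().astype(float)
    mask = _support_mask(volume, settings)
    labels, n_labels = ndimage.label(mask, structure=STRUCT_26)
    kept = []
    if n_labels:
        counts = np.bincount(labels.ravel())
        for lab in range(1, n_labels + 1):
            if settings.min_size_vox <= counts[lab] <= settings.max_size_vox:
                kept.append(lab)
    return labels, kept


# ---------------------------------------------------------------------------
# Nuclear-stain segmentation and per-nucleus foci counting
# ---------------------------------------------------------------------------


def count_foci_per_nucleus(
    nuclear_stain: ImageStack,
    foci_stain: ImageStack,
    min_focus_size_px: int = 3,
    min_nucleus_area_px: int = 200,
) -> list[dict]:
    """Count foci per nucleus on maximum intensity projections.

    Nuclei are segmented on the nuclear-stain MIP (global Otsu, hole
    filling, minimum area); foci are thresholded per nucleus (Otsu on
    the masked foci-stain pixels) and components with area strictly
    greater than *min_focus_size_px* are counted.

    Returns one record per nucleus: ``{"nucleus_id", "area_px",
    "centroid_xy", "n_foci"}``.  No nucleus found yields an empty list
    with a warning.
    """
    nuc = nuclear_stain.squeezed_spatial().astype(float).max(axis=0)
    foc = foci_stain.squeezed_spatial().astype(float).max(axis=0)
    if nuc.shape != foc.shape:
        raise ValueError("nuclear and foci stains must share spatial extents")

    if np.ptp(nuc) == 0:
        warnings.warn("nuclear stain is constant; no nucleus found")
        return []
    nuc_mask = nuc > threshold_otsu(nuc)
    nuc_mask = ndimage.binary_fill_holes(nuc_mask)
    nuc_labels, n_nuc = ndimage.label(nuc_mask)
    records: list[dict] = []
    for lab in range(1, n_nuc + 1):
        region = nuc_labels == lab
        area = int(region.sum())
        if area < min_nucleus_area_px:
            continue
        yy, xx = np.nonzero(region)
        pix = foc[region]
        n_foci = 0
        if np.ptp(pix) > 0:
            t = threshold_otsu(pix)
            foci_mask = region & (foc > t)
            foci_labels, n_comp = ndimage.label(foci_mask)
            if n_comp:
                sizes = np.bincount(foci_labels.ravel())[1:]
                n_foci = int((sizes > min_focus_size_px).sum())
        records.append(
            {
                "nucleus_id": lab,
                "area_px": area,
                "centroid_xy": (float(xx.mean()), float(yy.mean())),
                "n_foci": n_foci,
            }
        )
    if not records:
        warnings.warn("no nucleus found above the minimum area")
    return records
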