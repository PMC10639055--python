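"""In-memory model for microscopy image stacks and regions of interest.

Conventions used throughout the package:

* voxel indices are 0-based; ``(x, y)`` are column/row pixel centers;
* axis labels are a subset of ``t, c, z, y, x`` and are kept in that
  canonical order (missing axes simply omitted);
* physical units are micrometres for space and seconds for time, and
  conversions to/from anything else happen only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import shapely

AXIS_ORDER = "tczyx"
SPATIAL_AXES = "zyx"

#: acquisition defaults: 100x objective / EMCCD pixel in the sample plane,
#: confocal z-step, and the short FRAP protocol frame interval.
DEFAULT_PIXEL_SIZE_UM = 0.16
DEFAULT_Z_STEP_UM = 0.32
DEFAULT_FRAP_INTERVAL_S = 0.3


class AxisError(ValueError):
    """Raised when axis labels are missing, duplicated or unordered."""


class RoiValidationError(ValueError):
    """Raised when a region of interest violates its invariants."""


def canonical_axes(axes: str) -> str:
    """Return *axes* reordered to the canonical (t, c, z, y, x) order."""
    labels = list(axes)
    if len(set(labels)) != len(labels):
        raise AxisError(f"duplicate axis labels in {axes!r}")
    unknown = set(labels) - set(AXIS_ORDER)
    if unknown:
        raise AxisError(f"unknown axis labels {sorted(unknown)} in {axes!r}")
    return "".join(a for a in AXIS_ORDER if a in labels)


@dataclass
class ImageStack:
    """An n-dimensional voxel array with axis semantics and physical sizes.

    Parameters
    ----------
    data:
        Voxel array; unsigned integer or real valued.
    axes:
        Axis labels, one character per array dimension, drawn from
        ``t, c, z, y, x``.  The constructor transposes ``data`` into the
        canonical order if needed.
    voxel_size_um:
        Physical voxel size per spatial axis, micrometres.
    time_interval_s:
        Frame spacing for the ``t`` axis (seconds); ``None`` without one.
    bit_depth:
        Source bit depth (8 or 16 for camera data).
    """

    data: np.ndarray
    axes: str
    voxel_size_um: Mapping[str, float] = field(
        default_factory=lambda: {
            "z": DEFAULT_Z_STEP_UM,
            "y": DEFAULT_PIXEL_SIZE_UM,
            "x": DEFAULT_PIXEL_SIZE_UM,
        }
    )
    time_interval_s: float | None = None
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != len(self.axes):
            raise AxisError(
                f"axes {self.axes!r} do not match array of ndim {self.data.ndim}"
            )
        canon = canonical_axes(self.axes)
        if canon != self.axes:
            order = [self.axes.index(a) for a in canon]
            self.data = np.transpose(self.data, order)
            self.axes = canon
        if any(n < 1 for n in self.data.shape):
            raise ValueError("every axis must have extent >= 1")
        self.voxel_size_um = {
            a: float(self.voxel_size_um[a]) for a in SPATIAL_AXES if a in self.axes
        }
        for a, s in self.voxel_size_um.items():
            if not s > 0:
                raise ValueError(f"voxel_size_um[{a!r}] must be > 0, got {s}")
        if "t" not in self.axes:
            self.time_interval_s = None
        if self.bit_depth not in (8, 16, 32):
            raise ValueError(f"unsupported bit depth {self.bit_depth}")

    # -- axis helpers ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def axis_index(self, axis: str) -> int:
        if axis not in self.axes:
            raise AxisError(f"stack has no {axis!r} axis (axes={self.axes!r})")
        return self.axes.index(axis)

    def extent(self, axis: str) -> int:
        return self.data.shape[self.axis_index(axis)]

    def has_axis(self, axis: str) -> bool:
        return axis in self.axes

    def take(self, axis: str, index: int) -> "ImageStack":
        """Slice out one plane/frame along *axis*, dropping that axis."""
        i = self.axis_index(axis)
        return replace(
            self,
            data=np.take(self.data, index, axis=i),
            axes=self.axes.replace(axis, ""),
        )

    def squeezed_spatial(self) -> np.ndarray:
        """Return the voxel data for a single-channel single-frame stack
        as a (z, y, x) array (a missing z becomes a singleton)."""
        data, axes = self.data, self.axes
        for a in "tc":
            if a in axes:
                if data.shape[axes.index(a)] != 1:
                    raise AxisError(f"stack still has a non-singleton {a!r} axis")
                data = np.take(data, 0, axis=axes.index(a))
                axes = axes.replace(a, "")
        if axes == "yx":
            data = data[np.newaxis]
        elif axes != "zyx":
            raise AxisError(f"expected spatial axes, got {axes!r}")
        return data

    def frame_times_s(self) -> np.ndarray:
        """Times of the frames along ``t``, seconds, 0 at the first frame."""
        n = self.extent("t")
        dt = self.time_interval_s if self.time_interval_s else 1.0
        return np.arange(n) * float(dt)


# ---------------------------------------------------------------------------
# Regions of interest
# ---------------------------------------------------------------------------


@dataclass
class PolygonRoi:
    """A simple polygon in pixel coordinates, with an inclusive z range.

    ``z_range`` is either the string ``"all"`` or an inclusive
    ``(z_min, z_max)`` slice-index interval.
    """

    vertices: np.ndarray  # (n, 2) array of (x, y)
    z_range: tuple[int, int] | str = "all"
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise RoiValidationError("polygon needs >= 3 (x, y) vertices")
        self.vertices = v
        poly = shapely.Polygon(v)
        if not poly.is_valid:
            raise RoiValidationError(
                f"polygon {self.label!r} is not simple (self-intersecting?)"
            )
        if self.z_range != "all":
            z0, z1 = self.z_range
            if z1 < z0:
                raise RoiValidationError("z_range must be (z_min, z_max)")
            self.z_range = (int(z0), int(z1))

    @property
    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)

    def contains_point(self, x: float, y: float) -> bool:
        """Strict interior membership of a single point."""
        return bool(shapely.contains_xy(self.polygon, x, y))

    def contains_points(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return shapely.contains_xy(self.polygon, xy[:, 0], xy[:, 1])

    def contains_z(self, z: int, n_slices: int | None = None) -> bool:
        if self.z_range == "all":
            return True if n_slices is None else 0 <= z < n_slices
        z0, z1 = self.z_range
        return z0 <= z <= z1

    def mask(self, shape_yx: tuple[int, int]) -> np.ndarray:
        """Boolean (y, x) mask of pixels whose centers fall inside."""
        ny, nx = shape_yx
        yy, xx = np.mgrid[0:ny, 0:nx]
        inside = shapely.contains_xy(
            self.polygon, xx.ravel().astype(float), yy.ravel().astype(float)
        )
        return inside.reshape(ny, nx)

    def validate_against(self, stack: ImageStack) -> None:
        if self.z_range != "all" and stack.has_axis("z"):
            z0, z1 = self.z_range
            if z0 < 0 or z1 >= stack.extent("z"):
                raise RoiValidationError(
                    f"z_range {self.z_range} outside stack z extent "
                    f"{stack.extent('z')}"
                )


@dataclass
class CircleRoi:
    """A circular ROI, e.g. the photobleaching target region."""

    center: tuple[float, float]  # (x, y)
    diameter_px: int = 25
    z_index: int | str = "projection"
    label: str = ""

    def __post_init__(self) -> None:
        if self.diameter_px < 1:
            raise RoiValidationError("diameter_px must be >= 1")
        self.center = (float(self.center[0]), float(self.center[1]))

    @property
    def radius_px(self) -> float:
        return self.diameter_px / 2.0

    def mask(self, shape_yx: tuple[int, int]) -> np.ndarray:
        ny, nx = shape_yx
        yy, xx = np.mgrid[0:ny, 0:nx]
        cx, cy = self.center
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= self.radius_px**2

    def validate_against(self, stack: ImageStack) -> None:
        cx, cy = self.center
        r = self.radius_px
        ny, nx = stack.extent("y"), stack.extent("x")
        if cx - r < -0.5 or cx + r > nx - 0.5 or cy - r < -0.5 or cy + r > ny - 0.5:
            raise RoiValidationError("circle extends outside image bounds")


def rectangle_roi(
    x0: float, y0: float, x1: float, y1: float, label: str = ""
) -> PolygonRoi:
    """Convenience: an axis-aligned rectangular PolygonRoi."""
    return PolygonRoi(
        vertices=np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]]),
        label=label,
    )


def ellipse_roi(
    cx: float, cy: float, rx: float, ry: float, n_vertices: int = 48, label: str = ""
) -> PolygonRoi:
    """Convenience: a polygonal approximation of an ellipse."""
    th = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    verts = np.column_stack([cx + rx * np.cos(th), cy + ry * np.sin(th)])
    return PolygonRoi(vertices=verts, label=label)


Roi = PolygonRoi | CircleRoi


def as_roi_list(rois: Sequence[Roi] | Roi | None) -> list[Roi]:
    if rois is None:
        return []
    if isinstance(rois, (PolygonRoi, CircleRoi)):
        return [rois]
    return list(rois)
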