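"""Readers and writers: multi-page TIFF stacks, structured-text ROI files,
and the nested key-value configuration.

TIFF round trips are voxel exact for 8/16-bit unsigned data.  Stacks
written by this package carry their axis labels and physical calibration
in the (JSON) shaped metadata, so ``read_stack(write_stack(s))`` restores
``s`` including axis semantics.  Foreign TIFFs without usable metadata
need an ``axes_hint``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import tifffile
import yaml

from .stacks import (
    DEFAULT_FRAP_INTERVAL_S,
    DEFAULT_PIXEL_SIZE_UM,
    DEFAULT_Z_STEP_UM,
    CircleRoi,
    ImageStack,
    PolygonRoi,
    Roi,
    canonical_axes,
)


class FormatError(IOError):
    """Raised for unreadable or structurally invalid files."""


class DimensionError(ValueError):
    """Raised when a TIFF's dimensionality is ambiguous without a hint."""


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write *stack* as an uncompressed multi-page TIFF.

    Integer data must fit the declared bit depth; values are written
    losslessly.
    """
    path = Path(path)
    data = stack.data
    if np.issubdtype(data.dtype, np.integer):
        limit = 2**stack.bit_depth - 1
        if data.min() < 0 or data.max() > limit:
            raise ValueError(
                f"data range [{data.min()}, {data.max()}] exceeds "
                f"{stack.bit_depth}-bit depth"
            )
    meta = {
        "axes": stack.axes,
        "voxel_size_um": dict(stack.voxel_size_um),
        "time_interval_s": stack.time_interval_s,
        "bit_depth": stack.bit_depth,
    }
    try:
        tifffile.imwrite(path, data, metadata=meta, photometric="minisblack")
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise FormatError(f"cannot write TIFF to {path}: {exc}") from exc
    return path


def read_stack(path: str | Path, axes_hint: str | None = None) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`.

    Axis labels come, in order of preference, from this package's own
    metadata, from *axes_hint*, or from an unambiguous page structure
    (a single 2D page).  Anything else raises :class:`DimensionError`
    naming the candidate interpretations.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    except (tifffile.TiffFileError, OSError, IndexError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc

    voxel = meta.get("voxel_size_um")
    interval = meta.get("time_interval_s")
    bit_depth = meta.get("bit_depth") or (8 if data.dtype == np.uint8 else 16)

    axes = meta.get("axes")
    if axes is None:
        axes = axes_hint
    if axes is None:
        if data.ndim == 2:
            axes = "yx"
        else:
            candidates = [p + "yx" for p in ("z", "t", "c")]
            raise DimensionError(
                f"{path} has {data.ndim} dimensions and no axis metadata; "
                f"pass axes_hint (candidates for 3D: {candidates})"
            )
    axes = canonical_axes(axes) if sorted(axes) == sorted(canonical_axes(axes)) else axes
    if len(axes) != data.ndim:
        raise DimensionError(
            f"axes {axes!r} do not match data of ndim {data.ndim} in {path}"
        )
    kwargs: dict[str, Any] = {}
    if voxel:
        kwargs["voxel_size_um"] = voxel
    return ImageStack(
        data=data,
        axes=axes,
        time_interval_s=interval,
        bit_depth=int(bit_depth),
        **kwargs,
    )


# ---------------------------------------------------------------------------
# ROI files: one YAML document holding a list of records
# ---------------------------------------------------------------------------


def _roi_to_record(roi: Roi) -> dict[str, Any]:
    if isinstance(roi, PolygonRoi):
        return {
            "type": "polygon",
            "label": roi.label,
            "z_range": "all" if roi.z_range == "all" else list(roi.z_range),
            "vertices": [[float(x), float(y)] for x, y in roi.vertices],
        }
    return {
        "type": "circle",
        "label": roi.label,
        "center": [float(roi.center[0]), float(roi.center[1])],
        "diameter_px": int(roi.diameter_px),
        "z_index": roi.z_index,
    }


def _record_to_roi(rec: dict[str, Any]) -> Roi:
    kind = rec.get("type")
    if kind == "polygon":
        z = rec.get("z_range", "all")
        return PolygonRoi(
            vertices=np.asarray(rec["vertices"], dtype=float),
            z_range="all" if z == "all" else (int(z[0]), int(z[1])),
            label=rec.get("label", ""),
        )
    if kind == "circle":
        return CircleRoi(
            center=tuple(rec["center"]),
            diameter_px=int(rec["diameter_px"]),
            z_index=rec.get("z_index", "projection"),
            label=rec.get("label", ""),
        )
    raise FormatError(f"unknown ROI record type {kind!r}")


def write_rois(rois: Sequence[Roi], path: str | Path) -> Path:
    path = Path(path)
    records = [_roi_to_record(r) for r in rois]
    path.write_text(yaml.safe_dump(records, sort_keys=False))
    return path


def read_rois(path: str | Path) -> list[Roi]:
    """Read the structured-text ROI file; validates every record."""
    path = Path(path)
    try:
        records = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise FormatError(f"cannot read ROI file {path}: {exc}") from exc
    if records is None:
        return []
    if not isinstance(records, list):
        raise FormatError(f"ROI file {path} must hold a list of records")
    return [_record_to_roi(rec) for rec in records]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict[str, Any] = {
    "acquisition": {
        "pixel_size_um": DEFAULT_PIXEL_SIZE_UM,
        "z_step_um": DEFAULT_Z_STEP_UM,
        "frap_interval_s": DEFAULT_FRAP_INTERVAL_S,
        "frap_n_pre": 5,
        "frap_n_post": 120,
        "bleach_diameter_px": 25,
    },
    "detection": {
        # scale -> sensitivity; scale 1 (single pixels) disabled
        "sensitivity_per_scale": {2: 60.0, 3: 130.0},
        "min_size_vox": 2,
        "max_size_vox": 50,
        "force_2d": True,
        "noise_floor_frac": 0.1,
    },
    "telomere": {"k_sd": 2.0},
    "frap": {
        "terminal_window": 10,
        "fast_t80_cutoff_s": 36.0,
        "smooth_window": 1,
    },
    "locus": {
        "search_radius_px": 5,
        "measure_radius_px": 3,
        "smooth_window": 3,
        "min_prominence": 1.0,
    },
}


def deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a YAML config, merged over the package defaults."""
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    try:
        user = yaml.safe_load(Path(path).read_text()) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise FormatError(f"cannot read config {path}: {exc}") from exc
    return deep_merge(DEFAULT_CONFIG, user)


def write_sidecar(path: str | Path, payload: dict[str, Any]) -> Path:
    """Write a JSON sidecar with run metadata and echoed parameters."""
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, default=_jsonable))
    return path


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
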