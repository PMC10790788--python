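"""Slide heatmaps: ensemble fusion, per-pixel entropy, and raster I/O.

A slide is represented by two scalar maps: the *segmentation heatmap*
(per-pixel tumor probability, here the ensemble-mean softmax) and the
*uncertainty heatmap* (per-pixel entropy of that mean prediction, in nats).
This module defines the in-memory containers for both, the fusion and
entropy operations that produce them, and the on-disk bundle format used
by the rest of the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import tifffile
from PIL import Image
from scipy.special import xlogy

from .errors import InvalidInputError

__all__ = [
    "EnsembleStack",
    "ProbabilityMap",
    "UncertaintyMap",
    "fuse_ensemble",
    "pixel_entropy",
    "read_slide_bundle",
    "write_slide_bundle",
]

LN2 = float(np.log(2.0))


def _as_float_2d(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 2:
        raise InvalidInputError(f"{name} must be 2-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr


def _check_unit_range(arr: np.ndarray, name: str) -> None:
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        raise InvalidInputError(
            f"{name} values must lie in [0, 1]; observed range "
            f"[{arr.min():.6g}, {arr.max():.6g}]"
        )


@dataclass(frozen=True)
class EnsembleStack:
    """K per-pixel probability maps for one slide, stacked as (K, H, W)."""

    members: np.ndarray
    slide_id: str = ""

    def __post_init__(self):
        arr = np.asarray(self.members, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None, ...]
        if arr.ndim != 3:
            raise InvalidInputError(
                f"ensemble members must stack to (K, H, W), got shape {arr.shape}"
            )
        if arr.shape[0] < 1 or arr.shape[1] < 1 or arr.shape[2] < 1:
            raise InvalidInputError("ensemble stack must be non-empty")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("ensemble stack contains non-finite values")
        _check_unit_range(arr, "ensemble member")
        object.__setattr__(self, "members", arr)

    @classmethod
    def from_members(cls, maps: Sequence[np.ndarray], slide_id: str = "") -> "EnsembleStack":
        if len(maps) == 0:
            raise InvalidInputError("ensemble stack must contain at least one member")
        arrs = [_as_float_2d(m, "ensemble member") for m in maps]
        shapes = {a.shape for a in arrs}
        if len(shapes) > 1:
            raise InvalidInputError(f"ensemble members disagree on shape: {sorted(shapes)}")
        return cls(members=np.stack(arrs, axis=0), slide_id=slide_id)

    @property
    def k(self) -> int:
        return self.members.shape[0]

    @property
    def shape(self) -> tuple:
        return self.members.shape[1:]


@dataclass(frozen=True)
class ProbabilityMap:
    """Fused per-pixel tumor probability (the segmentation heatmap)."""

    values: np.ndarray
    slide_id: str = ""

    def __post_init__(self):
        arr = _as_float_2d(self.values, "probability map")
        _check_unit_range(arr, "probability map")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple:
        return self.values.shape


@dataclass(frozen=True)
class UncertaintyMap:
    """Per-pixel entropy of the fused prediction, in nats (the uncertainty heatmap)."""

    values: np.ndarray
    slide_id: str = ""

    def __post_init__(self):
        arr = _as_float_2d(self.values, "uncertainty map")
        if arr.size and arr.min() < -1e-12:
            raise InvalidInputError("uncertainty values must be non-negative")
        object.__setattr__(self, "values", np.maximum(arr, 0.0))

    @property
    def shape(self) -> tuple:
        return self.values.shape


def fuse_ensemble(stack: EnsembleStack) -> ProbabilityMap:
    """Fuse an ensemble by arithmetic per-pixel mean of member softmax maps."""
    if not isinstance(stack, EnsembleStack):
        stack = EnsembleStack.from_members(list(stack))
    fused = stack.members.mean(axis=0)
    return ProbabilityMap(values=fused, slide_id=stack.slide_id)


def pixel_entropy(pmap: ProbabilityMap) -> UncertaintyMap:
    """Binary entropy of the fused probability, per pixel.

    H(p) = -(p ln p + (1-p) ln(1-p)) in nats, with 0 ln 0 = 0, so
    H(0) = H(1) = 0 and H(0.5) = ln 2.
    """
    p = pmap.values
    h = -(xlogy(p, p) + xlogy(1.0 - p, 1.0 - p))
    return UncertaintyMap(values=h, slide_id=pmap.slide_id)


# ---------------------------------------------------------------------------
# Bundle I/O
#
# A slide bundle is a directory with a `layout.json` sidecar naming the files
# and their convention:
#   {"kind": "stack_tiff",   "stack": "stack.tif",  "mask": "gt.png"}
#   {"kind": "member_files", "members": ["m0.tif", ...], "mask": ...}
#   {"kind": "pmap_tiff",    "pmap": "pmap.tif", "mask": ...}
#   {"kind": "npz",          "archive": "slide.npz", ...}
# Integer rasters are interpreted as fixed-point scaled by their dtype max.

LAYOUT_FILE = "layout.json"


def _read_raster(path: Path) -> np.ndarray:
    if not path.exists():
        raise InvalidInputError(f"missing raster file: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        arr = np.asarray(Image.open(path))
    return arr


def _to_probability(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        return arr.astype(np.float64) / scale
    return arr.astype(np.float64)


def _binarize_mask(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.all(np.isfinite(arr.astype(np.float64))):
        raise InvalidInputError("ground-truth mask contains non-finite values")
    return (arr != 0).astype(np.uint8)


def read_slide_bundle(
    path: Union[str, Path],
    layout: Optional[dict] = None,
) -> tuple:
    """Read one slide bundle directory.

    Returns ``(maps, mask)`` where ``maps`` is an :class:`EnsembleStack` (for
    multi-member layouts) or a :class:`ProbabilityMap` (for fused layouts) and
    ``mask`` is a binarized ``{0,1}`` uint8 array or ``None``.
    """
    path = Path(path)
    if layout is None:
        sidecar = path / LAYOUT_FILE
        if not sidecar.exists():
            raise InvalidInputError(f"no layout sidecar found at {sidecar}")
        layout = json.loads(sidecar.read_text())
    kind = layout.get("kind")
    slide_id = layout.get("slide_id", path.name)

    mask = None
    if layout.get("mask"):
        mask = _binarize_mask(_read_raster(path / layout["mask"]))

    if kind == "stack_tiff":
        arr = _to_probability(_read_raster(path / layout["stack"]))
        if arr.ndim == 2:
            arr = arr[None, ...]
        maps: Union[EnsembleStack, ProbabilityMap] = EnsembleStack(
            members=arr, slide_id=slide_id
        )
    elif kind == "member_files":
        members = [_to_probability(_read_raster(path / f)) for f in layout["members"]]
        maps = EnsembleStack.from_members(members, slide_id=slide_id)
    elif kind == "pmap_tiff":
        maps = ProbabilityMap(values=_to_probability(_read_raster(path / layout["pmap"])), slide_id=slide_id)
    elif kind == "npz":
        with np.load(path / layout["archive"]) as z:
            if "members" in z:
                maps = EnsembleStack(members=z["members"].astype(np.float64), slide_id=slide_id)
            elif "pmap" in z:
                maps = ProbabilityMap(values=z["pmap"].astype(np.float64), slide_id=slide_id)
            else:
                raise InvalidInputError(
                    f"npz archive {layout['archive']} has neither 'members' nor 'pmap'"
                )
            if mask is None and "mask" in z:
                mask = _binarize_mask(z["mask"])
    else:
        raise InvalidInputError(f"unknown bundle layout kind: {kind!r}")

    shape = maps.shape
    if mask is not None and mask.shape != shape:
        raise InvalidInputError(
            f"mask shape {mask.shape} does not match map shape {shape}"
        )
    return maps, mask


def write_slide_bundle(
    path: Union[str, Path],
    maps: Union[EnsembleStack, ProbabilityMap],
    mask: Optional[np.ndarray] = None,
) -> dict:
    """Write a slide bundle in the canonical ``stack_tiff``/``pmap_tiff`` layout.

    Float maps are stored as float32 TIFF pages; the mask as a 0/255 PNG.
    Returns the layout dict that was written to the sidecar.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    layout: dict = {"slide_id": getattr(maps, "slide_id", path.name)}
    if isinstance(maps, EnsembleStack):
        layout["kind"] = "stack_tiff"
        layout["stack"] = "stack.tif"
        tifffile.imwrite(str(path / "stack.tif"), maps.members.astype(np.float32))
    elif isinstance(maps, ProbabilityMap):
        layout["kind"] = "pmap_tiff"
        layout["pmap"] = "pmap.tif"
        tifffile.imwrite(str(path / "pmap.tif"), maps.values.astype(np.float32))
    else:
        raise InvalidInputError(f"cannot write maps of type {type(maps).__name__}")
    if mask is not None:
        mask = _binarize_mask(mask)
        layout["mask"] = "gt.png"
        Image.fromarray((mask * 255).astype(np.uint8)).save(path / "gt.png")
    (path / LAYOUT_FILE).write_text(json.dumps(layout, indent=1, sort_keys=True))
    return layout
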