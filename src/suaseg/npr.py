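"""Negative-prediction-region (NPR) extraction.

An NPR is a connected component of pixels whose fused softmax lies strictly
between a lower bound ``t1`` and the positive-prediction threshold ``t2``.
Pixels at or above ``t2`` are positive predictions; pixels at or below ``t1``
are confident negatives; everything strictly in between is a candidate for
having been missed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict

import numpy as np
from skimage import measure

from .errors import InvalidConfigError, InvalidInputError
from .heatmap import ProbabilityMap

__all__ = ["ThresholdConfig", "NprLabelMap", "extract_nprs", "region_pixel_sets"]

_CONNECTIVITY = {4: 1, 8: 2}  # neighbour count -> skimage connectivity order


@dataclass(frozen=True)
class ThresholdConfig:
    """Thresholds and knobs shared across extraction, detection and refinement.

    Parameters
    ----------
    t1, t2
        Lower softmax bound and positive/segmentation threshold; NPR pixels
        satisfy ``t1 < p < t2`` (both strict).
    connectivity
        4 or 8 neighbours; 8 is the default.
    aggregation
        Region aggregate of pixel entropies: ``"mean"`` or ``"p90"``.
    tau
        Detection threshold on the aggregated entropy (nats); ``None`` means
        "calibrate on validation data".
    min_region_px
        Regions smaller than this many pixels are dropped.
    beta
        Beta of the F-beta calibration objective.
    fn_fraction
        Tumor fraction at or above which an NPR counts as a true FN region.
    """

    t1: float = 0.55
    t2: float = 0.95
    connectivity: int = 8
    aggregation: str = "mean"
    tau: float | None = None
    min_region_px: int = 1
    beta: float = 0.5
    fn_fraction: float = 0.9

    def __post_init__(self):
        if not (0.0 <= self.t1 < 1.0):
            raise InvalidConfigError(f"t1 must be in [0, 1), got {self.t1}")
        if not (0.0 < self.t2 <= 1.0):
            raise InvalidConfigError(f"t2 must be in (0, 1], got {self.t2}")
        if self.t1 >= self.t2:
            raise InvalidConfigError(f"t1 must be < t2, got t1={self.t1} t2={self.t2}")
        if self.connectivity not in _CONNECTIVITY:
            raise InvalidConfigError(f"connectivity must be 4 or 8, got {self.connectivity}")
        if self.aggregation not in ("mean", "p90"):
            raise InvalidConfigError(f"aggregation must be 'mean' or 'p90', got {self.aggregation!r}")
        if self.tau is not None and self.tau < 0:
            raise InvalidConfigError(f"tau must be >= 0, got {self.tau}")
        if self.min_region_px < 1:
            raise InvalidConfigError(f"min_region_px must be >= 1, got {self.min_region_px}")
        if self.beta <= 0:
            raise InvalidConfigError(f"beta must be > 0, got {self.beta}")
        if not (0.0 < self.fn_fraction <= 1.0):
            raise InvalidConfigError(f"fn_fraction must be in (0, 1], got {self.fn_fraction}")


@dataclass(frozen=True)
class NprLabelMap:
    """Integer label map: 0 = background, 1..R = NPR ids in raster order."""

    labels: np.ndarray
    slide_id: str = ""

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise InvalidInputError(f"label map must be 2-D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise InvalidInputError("label map must be integer-valued")
        if arr.size and arr.min() < 0:
            raise InvalidInputError("label map cannot contain negative labels")
        object.__setattr__(self, "labels", arr.astype(np.int32))

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())

    @property
    def shape(self) -> tuple:
        return self.labels.shape


def _compact_raster_order(labels: np.ndarray) -> np.ndarray:
    """Relabel to consecutive ids 1..R ordered by first raster occurrence."""
    flat = labels.ravel()
    nz = flat[flat > 0]
    if nz.size == 0:
        return labels
    # unique ids ordered by first occurrence in the flattened array
    order = nz[np.sort(np.unique(nz, return_index=True)[1])]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[order] = np.arange(1, order.size + 1, dtype=np.int32)
    return lut[labels]


def extract_nprs(pmap: ProbabilityMap, cfg: ThresholdConfig) -> NprLabelMap:
    """Label connected components of pixels with ``t1 < softmax < t2``.

    Both inequalities are strict: a pixel exactly at ``t2`` is a positive
    prediction and never part of an NPR; a pixel exactly at ``t1`` is a
    confident negative. Components smaller than ``cfg.min_region_px`` are
    dropped and ids re-compacted; ids are assigned in raster-scan order of
    first occurrence so output is deterministic.
    """
    v = pmap.values
    in_range = (v > cfg.t1) & (v < cfg.t2)
    labels = measure.label(in_range, connectivity=_CONNECTIVITY[cfg.connectivity])
    if cfg.min_region_px > 1 and labels.max() > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < cfg.min_region_px)
        kill = np.isin(labels, small[small > 0])
        labels = np.where(kill, 0, labels)
    labels = _compact_raster_order(np.asarray(labels))
    return NprLabelMap(labels=labels, slide_id=pmap.slide_id)


def region_pixel_sets(label_map: NprLabelMap) -> Dict[int, np.ndarray]:
    """Partition labeled pixels into per-region ``(n_i, 2)`` coordinate arrays."""
    labels = label_map.labels
    out: Dict[int, np.ndarray] = {}
    for rid in range(1, label_map.n_regions + 1):
        rows, cols = np.nonzero(labels == rid)
        out[rid] = np.stack([rows, cols], axis=1)
    return out
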