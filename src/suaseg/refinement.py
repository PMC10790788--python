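"""Segmentation-heatmap refinement from detected FN regions or pixels.

Refinement only ever adds positives: every pixel of a flagged NPR (region
route) or every flagged pixel (baseline route) has its prediction updated to
positive, with probability 1.0 in the refined heatmap. Pixels that are
already positive (softmax >= t2) are never touched, which makes refinement
idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidInputError
from .heatmap import ProbabilityMap
from .npr import NprLabelMap, ThresholdConfig
from .detection import RegionRecord

__all__ = ["RefinementResult", "refine_sua", "refine_baseline"]


@dataclass(frozen=True)
class RefinementResult:
    """Outcome of one refinement pass over a slide."""

    refined_binary: np.ndarray  # {0,1} positive-prediction mask
    refined_pmap: ProbabilityMap
    updated_pixels: np.ndarray  # (n, 2) row/col coordinates, raster order
    provenance: str  # "sua" | "baseline"
    slide_id: str = ""

    @property
    def n_updated(self) -> int:
        return int(self.updated_pixels.shape[0])


def _apply_update(
    pmap: ProbabilityMap, add_mask: np.ndarray, cfg: ThresholdConfig, provenance: str
) -> RefinementResult:
    original_pos = pmap.values >= cfg.t2
    updated = add_mask & ~original_pos
    refined_binary = (original_pos | add_mask).astype(np.uint8)
    refined_values = pmap.values.copy()
    refined_values[updated] = 1.0
    rows, cols = np.nonzero(updated)
    return RefinementResult(
        refined_binary=refined_binary,
        refined_pmap=ProbabilityMap(values=refined_values, slide_id=pmap.slide_id),
        updated_pixels=np.stack([rows, cols], axis=1),
        provenance=provenance,
        slide_id=pmap.slide_id,
    )


def refine_sua(
    pmap: ProbabilityMap,
    label_map: NprLabelMap,
    records: Sequence[RegionRecord],
    cfg: ThresholdConfig,
) -> RefinementResult:
    """Convert every pixel of every FN-flagged NPR to a positive prediction."""
    if label_map.shape != pmap.shape:
        raise InvalidInputError(
            f"label map shape {label_map.shape} != pmap shape {pmap.shape}"
        )
    if any(r.is_fn_predicted is None for r in records):
        raise InvalidInputError("records must carry is_fn_predicted; run detect_fn first")
    present = set(range(1, label_map.n_regions + 1))
    rec_ids = {r.region_id for r in records}
    if not rec_ids <= present:
        raise InvalidInputError(
            f"records reference region ids absent from the label map: "
            f"{sorted(rec_ids - present)}"
        )
    flagged = sorted(r.region_id for r in records if r.is_fn_predicted)
    add_mask = np.isin(label_map.labels, flagged) if flagged else np.zeros(
        pmap.shape, dtype=bool
    )
    return _apply_update(pmap, add_mask, cfg, "sua")


def refine_baseline(
    pmap: ProbabilityMap,
    pixel_mask: np.ndarray,
    cfg: ThresholdConfig,
) -> RefinementResult:
    """Convert each individually flagged pixel to a positive prediction."""
    pixel_mask = np.asarray(pixel_mask).astype(bool)
    if pixel_mask.shape != pmap.shape:
        raise InvalidInputError(
            f"pixel mask shape {pixel_mask.shape} != pmap shape {pmap.shape}"
        )
    return _apply_update(pmap, pixel_mask, cfg, "baseline")
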