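"""FN-region detection by spatially aggregated uncertainty, plus the
independent-pixel baseline.

Each NPR is scored by an aggregate (mean or 90th percentile) of its pixels'
entropies; regions whose score is strictly above a threshold ``tau`` are
flagged as false-negative regions. ``tau`` is calibrated on validation data
by maximizing the F-beta score (beta = 0.5 by default, weighting precision).
The baseline applies the same idea per pixel, with no spatial grouping: an
eligible pixel (``t1 < softmax < t2``) is flagged iff its own entropy
exceeds a pixel-level threshold calibrated the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    CalibrationError,
    GroundTruthUnavailableError,
    InvalidInputError,
)
from .heatmap import ProbabilityMap, UncertaintyMap
from .npr import NprLabelMap, ThresholdConfig

__all__ = [
    "RegionRecord",
    "aggregate_region_uncertainty",
    "label_fn_truth",
    "calibrate_tau",
    "calibration_curve",
    "detect_fn",
    "eligible_pixel_mask",
    "calibrate_tau_pixel",
    "baseline_detect_fn_pixels",
]


@dataclass(frozen=True)
class RegionRecord:
    """Per-NPR summary used for calibration, detection and reporting."""

    slide_id: str
    region_id: int
    n_pixels: int
    agg_uncertainty: float
    tumor_fraction: Optional[float] = None
    is_fn_truth: Optional[bool] = None
    is_fn_predicted: Optional[bool] = None

    def __post_init__(self):
        if self.n_pixels < 1:
            raise InvalidInputError("region must contain at least one pixel")
        if self.agg_uncertainty < 0:
            raise InvalidInputError("aggregated uncertainty must be non-negative")


def _aggregate(values: np.ndarray, method: str) -> float:
    if method == "mean":
        return float(values.mean())
    if method == "p90":
        # linear interpolation between order statistics
        return float(np.percentile(values, 90.0, method="linear"))
    raise InvalidInputError(f"unknown aggregation method {method!r}")


def aggregate_region_uncertainty(
    label_map: NprLabelMap,
    umap: UncertaintyMap,
    method: str = "mean",
) -> List[RegionRecord]:
    """Aggregate per-pixel entropy within each NPR.

    Returns one :class:`RegionRecord` per region id (ascending), with
    ``agg_uncertainty`` filled and the truth/prediction fields unset.
    """
    if label_map.shape != umap.shape:
        raise InvalidInputError(
            f"label map shape {label_map.shape} != uncertainty shape {umap.shape}"
        )
    labels = label_map.labels
    records = []
    for rid in range(1, label_map.n_regions + 1):
        vals = umap.values[labels == rid]
        records.append(
            RegionRecord(
                slide_id=label_map.slide_id,
                region_id=rid,
                n_pixels=int(vals.size),
                agg_uncertainty=_aggregate(vals, method),
            )
        )
    return records


def label_fn_truth(
    records: Sequence[RegionRecord],
    label_map: NprLabelMap,
    gt_mask: Optional[np.ndarray],
    fn_fraction: float = 0.9,
) -> List[RegionRecord]:
    """Attach ground-truth tumor fraction and the FN-truth flag to records.

    A region is a true FN region iff at least ``fn_fraction`` of its pixels
    (default 90%) are ground-truth tumor; the bound is inclusive.
    """
    if gt_mask is None:
        raise GroundTruthUnavailableError(
            "ground-truth mask required to label FN truth"
        )
    gt = np.asarray(gt_mask)
    if gt.shape != label_map.shape:
        raise InvalidInputError(
            f"ground-truth shape {gt.shape} != label map shape {label_map.shape}"
        )
    gt = (gt != 0)
    labels = label_map.labels
    out = []
    for rec in records:
        member = labels == rec.region_id
        n = int(member.sum())
        if n != rec.n_pixels:
            raise InvalidInputError(
                f"record for region {rec.region_id} does not match label map "
                f"({rec.n_pixels} vs {n} pixels)"
            )
        frac = float(gt[member].sum()) / n
        out.append(
            replace(rec, tumor_fraction=frac, is_fn_truth=bool(frac >= fn_fraction))
        )
    return out


def _fbeta_from_flags(truth: np.ndarray, pred: np.ndarray, beta: float) -> float:
    tp = int(np.sum(truth & pred))
    fp = int(np.sum(~truth & pred))
    fn = int(np.sum(truth & ~pred))
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    b2 = beta * beta
    return (1.0 + b2) * precision * recall / (b2 * precision + recall)


def _scan_candidates(scores: np.ndarray) -> np.ndarray:
    """Threshold candidates: midpoints between consecutive unique scores,
    plus one candidate below the minimum (flag-everything regime)."""
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0 if u.size > 1 else np.empty(0)
    below = max(u[0] - max(u[0] * 0.5, 1e-6), 0.0) if u[0] > 0 else 0.0
    return np.concatenate([[below], mids])


def _calibrate_threshold(
    scores: np.ndarray, truth: np.ndarray, beta: float
) -> Tuple[float, float, np.ndarray, np.ndarray]:
    if truth.all() or not truth.any():
        raise CalibrationError(
            "calibration requires both FN and TN examples in the validation set"
        )
    candidates = _scan_candidates(scores)
    fbetas = np.array(
        [_fbeta_from_flags(truth, scores > c, beta) for c in candidates]
    )
    best = fbetas.max()
    # ties broken toward the larger tau (higher precision)
    tau = float(candidates[np.flatnonzero(fbetas == best).max()])
    return tau, float(best), candidates, fbetas


def calibrate_tau(
    validation_records: Sequence[RegionRecord], beta: float = 0.5
) -> float:
    """Pick the detection threshold maximizing F-beta on validation records.

    Candidates are scanned over midpoints of the sorted unique aggregated
    uncertainties (plus a flag-everything candidate below the minimum);
    ties are broken toward the larger tau.
    """
    scores, truth = _records_to_arrays(validation_records)
    tau, _, _, _ = _calibrate_threshold(scores, truth, beta)
    return tau


def calibration_curve(
    validation_records: Sequence[RegionRecord], beta: float = 0.5
) -> dict:
    """Full calibration report: chosen tau, its F-beta, and the scan curve."""
    scores, truth = _records_to_arrays(validation_records)
    tau, best, candidates, fbetas = _calibrate_threshold(scores, truth, beta)
    return {
        "tau": tau,
        "fbeta": best,
        "beta": beta,
        "candidates": candidates.tolist(),
        "fbetas": fbetas.tolist(),
        "n_records": int(len(validation_records)),
        "n_fn_truth": int(truth.sum()),
    }


def _records_to_arrays(records: Sequence[RegionRecord]) -> Tuple[np.ndarray, np.ndarray]:
    if len(records) == 0:
        raise CalibrationError("no validation records supplied")
    if any(r.is_fn_truth is None for r in records):
        raise GroundTruthUnavailableError(
            "validation records must carry is_fn_truth; run label_fn_truth first"
        )
    scores = np.array([r.agg_uncertainty for r in records], dtype=np.float64)
    truth = np.array([bool(r.is_fn_truth) for r in records])
    return scores, truth


def detect_fn(records: Sequence[RegionRecord], tau: float) -> List[RegionRecord]:
    """Flag regions whose aggregated uncertainty is strictly above ``tau``."""
    return [
        replace(rec, is_fn_predicted=bool(rec.agg_uncertainty > tau))
        for rec in records
    ]


# ---------------------------------------------------------------------------
# Independent-pixel baseline


def eligible_pixel_mask(pmap: ProbabilityMap, cfg: ThresholdConfig) -> np.ndarray:
    """Pixels eligible for the baseline: exactly the NPR membership rule."""
    v = pmap.values
    return (v > cfg.t1) & (v < cfg.t2)


def calibrate_tau_pixel(
    pmaps: Sequence[ProbabilityMap],
    umaps: Sequence[UncertaintyMap],
    gt_masks: Sequence[np.ndarray],
    cfg: ThresholdConfig,
    beta: float = 0.5,
) -> float:
    """Calibrate the baseline's pixel-entropy threshold on validation slides.

    Pixel-level truth is ground-truth tumor membership among eligible pixels;
    the F-beta scan is identical to the region-level calibration.
    """
    scores, truth = [], []
    for pmap, umap, gt in zip(pmaps, umaps, gt_masks):
        if gt is None:
            raise GroundTruthUnavailableError(
                "ground truth required for baseline calibration"
            )
        gt = np.asarray(gt) != 0
        if gt.shape != pmap.shape or umap.shape != pmap.shape:
            raise InvalidInputError("pmap/umap/mask shapes disagree")
        elig = eligible_pixel_mask(pmap, cfg)
        scores.append(umap.values[elig])
        truth.append(gt[elig])
    scores = np.concatenate(scores)
    truth = np.concatenate(truth)
    if scores.size == 0:
        raise CalibrationError("no eligible pixels on the validation slides")
    tau, _, _, _ = _calibrate_threshold(scores, truth, beta)
    return tau


def baseline_detect_fn_pixels(
    pmap: ProbabilityMap,
    umap: UncertaintyMap,
    cfg: ThresholdConfig,
    tau_pixel: float,
) -> np.ndarray:
    """Flag eligible pixels whose own entropy is strictly above ``tau_pixel``."""
    if umap.shape != pmap.shape:
        raise InvalidInputError(
            f"pmap shape {pmap.shape} != umap shape {umap.shape}"
        )
    return eligible_pixel_mask(pmap, cfg) & (umap.values > tau_pixel)
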