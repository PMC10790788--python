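"""Evaluation metrics: F-beta, Dice, FNCR, lesion-level FROC, slide-level
ROC-AUC, and slide-resampling bootstrap summaries.

FNCR (false-negative conversion rate) is pooled over the dataset:
``sum_i N+_i / sum_i Ntotal_i`` where ``N+_i`` counts updated pixels that
are ground-truth tumor on slide i and ``Ntotal_i`` all updated pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from skimage import measure
from sklearn.metrics import roc_auc_score

from .errors import InvalidInputError, UndefinedMetricError
from .heatmap import ProbabilityMap
from .refinement import RefinementResult

__all__ = [
    "ConfusionCounts",
    "BootstrapReport",
    "f_beta",
    "dice",
    "fncr",
    "froc_score",
    "slide_roc_auc",
    "bootstrap",
    "detections_from_heatmap",
]

DEFAULT_FP_POINTS = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel- or region-level confusion counts."""

    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InvalidInputError("confusion counts must be non-negative")

    @classmethod
    def from_masks(cls, pred, gt) -> "ConfusionCounts":
        pred = np.asarray(pred).astype(bool)
        gt = np.asarray(gt).astype(bool)
        if pred.shape != gt.shape:
            raise InvalidInputError(
                f"prediction shape {pred.shape} != ground-truth shape {gt.shape}"
            )
        return cls(
            tp=int(np.sum(pred & gt)),
            fp=int(np.sum(pred & ~gt)),
            fn=int(np.sum(~pred & gt)),
            tn=int(np.sum(~pred & ~gt)),
        )

    @classmethod
    def from_flags(cls, truth: Sequence[bool], pred: Sequence[bool]) -> "ConfusionCounts":
        truth = np.asarray(truth, dtype=bool)
        pred = np.asarray(pred, dtype=bool)
        if truth.shape != pred.shape:
            raise InvalidInputError("truth and prediction flag vectors differ in length")
        return cls.from_masks(pred, truth)

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


def f_beta(counts: ConfusionCounts, beta: float = 0.5) -> float:
    """F-beta score; beta < 1 weights precision more than recall.

    Returns 0.0 when tp == 0 but errors exist; undefined when tp+fp+fn == 0.
    """
    if counts.tp + counts.fp + counts.fn == 0:
        raise UndefinedMetricError("F-beta undefined: no positives in truth or prediction")
    if counts.tp == 0:
        return 0.0
    precision = counts.tp / (counts.tp + counts.fp)
    recall = counts.tp / (counts.tp + counts.fn)
    b2 = beta * beta
    return (1.0 + b2) * precision * recall / (b2 * precision + recall)


def dice(pred, gt) -> float:
    """Dice coefficient 2TP/(2TP+FP+FN); two empty masks score 1.0."""
    c = ConfusionCounts.from_masks(pred, gt)
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2.0 * c.tp / denom


def _fncr_counts(
    results: Sequence[RefinementResult], gt_masks: Sequence[np.ndarray]
) -> Tuple[int, int]:
    if len(results) != len(gt_masks):
        raise InvalidInputError("one ground-truth mask required per refinement result")
    n_plus = n_total = 0
    for res, gt in zip(results, gt_masks):
        gt = np.asarray(gt).astype(bool)
        if gt.shape != res.refined_binary.shape:
            raise InvalidInputError("ground-truth mask shape mismatch in FNCR")
        coords = res.updated_pixels
        n_total += coords.shape[0]
        if coords.shape[0]:
            n_plus += int(gt[coords[:, 0], coords[:, 1]].sum())
    return n_plus, n_total


def fncr(results: Sequence[RefinementResult], gt_masks: Sequence[np.ndarray]) -> float:
    """Pooled false-negative conversion rate over a slide set."""
    n_plus, n_total = _fncr_counts(results, gt_masks)
    if n_total == 0:
        raise UndefinedMetricError("FNCR undefined: no pixels were updated")
    return n_plus / n_total


# ---------------------------------------------------------------------------
# Lesion-level FROC


def detections_from_heatmap(
    pmap: ProbabilityMap, threshold: float
) -> List[Tuple[int, int, float]]:
    """One detection per positive connected component: the coordinate of its
    maximum probability, with that maximum as confidence."""
    binary = pmap.values >= threshold
    labels = measure.label(binary, connectivity=2)
    dets = []
    for rid in range(1, int(labels.max()) + 1):
        member = labels == rid
        vals = np.where(member, pmap.values, -np.inf)
        idx = np.unravel_index(int(np.argmax(vals)), vals.shape)
        dets.append((int(idx[0]), int(idx[1]), float(pmap.values[idx])))
    return dets


def froc_score(
    detections: Mapping[str, Sequence[Tuple[int, int, float]]],
    lesion_labels: Mapping[str, np.ndarray],
    fp_points: Sequence[float] = DEFAULT_FP_POINTS,
) -> float:
    """Mean lesion sensitivity at fixed average-FP-per-slide operating points.

    ``detections`` maps slide id to ``(row, col, confidence)`` triples;
    ``lesion_labels`` maps slide id to an integer-labeled lesion map (0 =
    background). A lesion is hit at a confidence threshold if any detection
    at or above that threshold falls inside it; detections outside every
    lesion are false positives. Sensitivity is interpolated at each
    operating point and averaged.
    """
    slide_ids = sorted(lesion_labels)
    n_slides = len(slide_ids)
    if n_slides == 0:
        raise UndefinedMetricError("FROC undefined: no slides")
    total_lesions = sum(int(np.asarray(lesion_labels[s]).max()) for s in slide_ids)
    if total_lesions == 0:
        raise UndefinedMetricError("FROC undefined: no lesions in the dataset")

    # per detection: confidence, and the lesion it hits (slide, lesion id) or None
    confs, hit_keys = [], []
    for sid in slide_ids:
        lmap = np.asarray(lesion_labels[sid])
        for row, col, conf in detections.get(sid, ()):  # type: ignore[arg-type]
            if not (0 <= row < lmap.shape[0] and 0 <= col < lmap.shape[1]):
                raise InvalidInputError(
                    f"detection ({row},{col}) outside slide {sid} of shape {lmap.shape}"
                )
            lid = int(lmap[row, col])
            confs.append(float(conf))
            hit_keys.append((sid, lid) if lid > 0 else None)
    if not confs:
        return 0.0
    confs_arr = np.asarray(confs)

    sens_curve, fp_curve = [], []
    for thr in np.unique(confs_arr):
        keep = confs_arr >= thr
        hits = {hit_keys[i] for i in np.flatnonzero(keep) if hit_keys[i] is not None}
        n_fp = int(sum(1 for i in np.flatnonzero(keep) if hit_keys[i] is None))
        sens_curve.append(len(hits) / total_lesions)
        fp_curve.append(n_fp / n_slides)
    # sort by average FPs ascending; thresholds that only add hits keep the
    # FP level constant, so keep the best sensitivity per FP level
    order = np.argsort(fp_curve, kind="stable")
    fps_all = np.asarray(fp_curve)[order]
    sens_all = np.asarray(sens_curve)[order]
    fps, sens = [], []
    for f, s in zip(fps_all, sens_all):
        if fps and fps[-1] == f:
            sens[-1] = max(sens[-1], s)
        else:
            fps.append(f)
            sens.append(s)
    # below the smallest achieved FP rate, sensitivity falls to the most
    # conservative operating point's value; above the largest, it saturates
    interp = np.interp(np.asarray(fp_points, dtype=float), fps, sens)
    return float(interp.mean())


def slide_roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based ROC-AUC of slide-level scores against tumor/normal labels."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0 or len(np.unique(labels)) < 2:
        raise UndefinedMetricError("ROC-AUC undefined: need both slide classes")
    return float(roc_auc_score(labels, scores))


# ---------------------------------------------------------------------------
# Bootstrap


@dataclass(frozen=True)
class BootstrapReport:
    """Point estimate plus bootstrap mean/SD of a slide-level statistic."""

    metric: str
    point: float
    boot_mean: float
    boot_sd: float
    n_boot: int
    seed: int
    n_slides: int

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "point": self.point,
            "boot_mean": self.boot_mean,
            "boot_sd": self.boot_sd,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_slides": self.n_slides,
        }


def bootstrap(
    slide_inputs: Sequence,
    statistic: Callable[[Sequence], float],
    n_boot: int = 1000,
    seed: int = 0,
    metric: str = "",
) -> BootstrapReport:
    """Resample slides with replacement and recompute ``statistic`` each time.

    ``statistic`` receives a list of per-slide inputs (whatever the metric
    needs — pooled formulas are re-pooled per resample) and returns a float.
    Resamples on which the statistic is undefined are skipped.
    """
    n = len(slide_inputs)
    if n == 0:
        raise InvalidInputError("bootstrap requires at least one slide")
    point = float(statistic(list(slide_inputs)))
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            vals.append(float(statistic([slide_inputs[i] for i in idx])))
        except UndefinedMetricError:
            continue
    if not vals:
        raise UndefinedMetricError("statistic undefined on every bootstrap resample")
    arr = np.asarray(vals)
    return BootstrapReport(
        metric=metric,
        point=point,
        boot_mean=float(arr.mean()),
        boot_sd=float(arr.std(ddof=0)),
        n_boot=n_boot,
        seed=seed,
        n_slides=n,
    )
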