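"""End-to-end run orchestration: load -> fuse -> extract -> calibrate ->
detect -> refine -> evaluate, with all artifacts written to disk.

This module is the engine behind the ``suaseg run`` command; each stage is
also reachable through the finer-grained CLI subcommands.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from skimage import measure

from . import detection as det
from . import evaluation as ev
from . import refinement as ref
from .errors import InvalidConfigError, SuasegError, UndefinedMetricError
from .heatmap import (
    EnsembleStack,
    ProbabilityMap,
    UncertaintyMap,
    fuse_ensemble,
    pixel_entropy,
    read_slide_bundle,
    write_slide_bundle,
)
from .npr import NprLabelMap, ThresholdConfig, extract_nprs

__all__ = ["RunConfig", "SlideData", "load_slides", "process_slide", "run_pipeline", "regions_dataframe"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run."""

    input_dir: str
    output_dir: str
    t1: float = 0.55
    t2: float = 0.95
    connectivity: int = 8
    aggregation: str = "mean"
    tau: Optional[float] = None
    tau_pixel: Optional[float] = None
    min_region_px: int = 1
    beta: float = 0.5
    fn_fraction: float = 0.9
    n_boot: int = 1000
    seed: int = 0
    mode: str = "both"  # sua | baseline | both
    val_fraction: float = 0.5

    def __post_init__(self):
        if self.mode not in ("sua", "baseline", "both"):
            raise InvalidConfigError(f"mode must be sua|baseline|both, got {self.mode!r}")
        if not (0.0 < self.val_fraction < 1.0):
            raise InvalidConfigError("val_fraction must lie in (0, 1)")
        if self.n_boot < 1:
            raise InvalidConfigError("n_boot must be >= 1")
        self.thresholds()  # validates threshold fields

    def thresholds(self) -> ThresholdConfig:
        return ThresholdConfig(
            t1=self.t1,
            t2=self.t2,
            connectivity=self.connectivity,
            aggregation=self.aggregation,
            tau=self.tau,
            min_region_px=self.min_region_px,
            beta=self.beta,
            fn_fraction=self.fn_fraction,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = {"input_dir", "output_dir"} - set(raw)
        if missing:
            raise InvalidConfigError(f"missing required config keys: {sorted(missing)}")
        return cls(**raw)


@dataclass
class SlideData:
    """Everything the pipeline knows about one slide."""

    slide_id: str
    pmap: ProbabilityMap
    umap: UncertaintyMap
    gt: Optional[np.ndarray] = None
    labels: Optional[NprLabelMap] = None
    records: List[det.RegionRecord] = field(default_factory=list)

    @property
    def has_gt(self) -> bool:
        return self.gt is not None


def load_slides(input_dir, cfg: Optional[RunConfig] = None) -> List[SlideData]:
    """Read every slide bundle (any subdirectory with a layout sidecar)."""
    input_dir = Path(input_dir)
    slide_dirs = sorted(
        d for d in input_dir.iterdir() if d.is_dir() and (d / "layout.json").exists()
    )
    if not slide_dirs:
        raise InvalidConfigError(f"no slide bundles found under {input_dir}")
    slides = []
    for d in slide_dirs:
        maps, mask = read_slide_bundle(d)
        pmap = fuse_ensemble(maps) if isinstance(maps, EnsembleStack) else maps
        slides.append(
            SlideData(
                slide_id=pmap.slide_id or d.name,
                pmap=pmap,
                umap=pixel_entropy(pmap),
                gt=mask,
            )
        )
    return slides


def process_slide(slide: SlideData, tcfg: ThresholdConfig) -> SlideData:
    """Extract NPRs and aggregate region uncertainty (plus truth, if present)."""
    slide.labels = extract_nprs(slide.pmap, tcfg)
    slide.records = det.aggregate_region_uncertainty(
        slide.labels, slide.umap, method=tcfg.aggregation
    )
    if slide.has_gt and slide.records:
        slide.records = det.label_fn_truth(
            slide.records, slide.labels, slide.gt, fn_fraction=tcfg.fn_fraction
        )
    return slide


def regions_dataframe(slides: Sequence[SlideData]) -> pd.DataFrame:
    """Per-region export table with both aggregates, truth and predictions."""
    rows = []
    for s in slides:
        if s.labels is None:
            continue
        p90 = {
            r.region_id: r.agg_uncertainty
            for r in det.aggregate_region_uncertainty(s.labels, s.umap, method="p90")
        }
        mean = {
            r.region_id: r.agg_uncertainty
            for r in det.aggregate_region_uncertainty(s.labels, s.umap, method="mean")
        }
        for r in s.records:
            rows.append(
                {
                    "slide_id": s.slide_id,
                    "region_id": r.region_id,
                    "n_pixels": r.n_pixels,
                    "mean_entropy": mean[r.region_id],
                    "p90_entropy": p90[r.region_id],
                    "tumor_fraction": r.tumor_fraction,
                    "is_fn_truth": r.is_fn_truth,
                    "is_fn_predicted": r.is_fn_predicted,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "slide_id",
            "region_id",
            "n_pixels",
            "mean_entropy",
            "p90_entropy",
            "tumor_fraction",
            "is_fn_truth",
            "is_fn_predicted",
        ],
    )


def split_slides(
    slides: Sequence[SlideData], val_fraction: float, seed: int
) -> Tuple[List[SlideData], List[SlideData]]:
    """Seeded validation/test split at the slide level.

    With a single slide, it serves as both validation and test (degenerate
    but useful for smoke runs)."""
    n = len(slides)
    if n == 1:
        return list(slides), list(slides)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = int(np.clip(round(val_fraction * n), 1, n - 1))
    val_idx = sorted(perm[:n_val])
    test_idx = sorted(perm[n_val:])
    return [slides[i] for i in val_idx], [slides[i] for i in test_idx]


# ---------------------------------------------------------------------------
# Metric helpers (statistics expressed over per-slide inputs so they can be
# re-pooled inside the bootstrap)


def _pooled_region_fbeta(slide_flags: Sequence[Tuple[np.ndarray, np.ndarray]], beta: float) -> float:
    truths = [t for t, _ in slide_flags]
    preds = [p for _, p in slide_flags]
    truth = np.concatenate(truths) if truths else np.empty(0, bool)
    pred = np.concatenate(preds) if preds else np.empty(0, bool)
    return ev.f_beta(ev.ConfusionCounts.from_flags(truth, pred), beta=beta)


def _mean_dice(slide_masks: Sequence[Tuple[np.ndarray, np.ndarray]]) -> float:
    return float(np.mean([ev.dice(p, g) for p, g in slide_masks]))


def _pooled_fncr(counts: Sequence[Tuple[int, int]]) -> float:
    n_plus = sum(c[0] for c in counts)
    n_total = sum(c[1] for c in counts)
    if n_total == 0:
        raise UndefinedMetricError("FNCR undefined: no pixels updated")
    return n_plus / n_total


def _fncr_slide_counts(result: ref.RefinementResult, gt: np.ndarray) -> Tuple[int, int]:
    gt = np.asarray(gt).astype(bool)
    coords = result.updated_pixels
    n_total = int(coords.shape[0])
    n_plus = int(gt[coords[:, 0], coords[:, 1]].sum()) if n_total else 0
    return n_plus, n_total


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline and write all artifacts under output_dir.

    Returns the metrics dictionary that is also saved as ``metrics.json``.
    """
    tcfg = cfg.thresholds()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    slides = load_slides(cfg.input_dir, cfg)
    for s in slides:
        process_slide(s, tcfg)
    val, test = split_slides(slides, cfg.val_fraction, cfg.seed)
    any_gt = all(s.has_gt for s in slides)

    log: List[str] = []
    log.append(
        f"loaded {len(slides)} slides "
        f"({sum(len(s.records) for s in slides)} NPRs total); "
        f"{len(val)} validation / {len(test)} test"
    )

    calibration: dict = {"beta": cfg.beta, "aggregation": cfg.aggregation}
    run_sua = cfg.mode in ("sua", "both")
    run_baseline = cfg.mode in ("baseline", "both")

    # --- calibrate -----------------------------------------------------
    tau = cfg.tau
    if run_sua and tau is None:
        val_records = [r for s in val for r in s.records]
        if not any_gt:
            raise InvalidConfigError(
                "tau must be given explicitly when ground truth is unavailable"
            )
        curve = det.calibration_curve(val_records, beta=cfg.beta)
        tau = curve["tau"]
        calibration["sua"] = curve
    elif run_sua:
        calibration["sua"] = {"tau": tau, "source": "config"}

    tau_pixel = cfg.tau_pixel
    if run_baseline and tau_pixel is None:
        if not any_gt:
            raise InvalidConfigError(
                "tau_pixel must be given explicitly when ground truth is unavailable"
            )
        tau_pixel = det.calibrate_tau_pixel(
            [s.pmap for s in val], [s.umap for s in val], [s.gt for s in val],
            tcfg, beta=cfg.beta,
        )
        calibration["baseline"] = {"tau_pixel": tau_pixel}
    elif run_baseline:
        calibration["baseline"] = {"tau_pixel": tau_pixel, "source": "config"}

    # --- detect + refine on the test slides ----------------------------
    sua_results: Dict[str, ref.RefinementResult] = {}
    base_results: Dict[str, ref.RefinementResult] = {}
    update_rows = []
    for s in test:
        if run_sua:
            s.records = det.detect_fn(s.records, tau)
            res = ref.refine_sua(s.pmap, s.labels, s.records, tcfg)
            sua_results[s.slide_id] = res
            write_slide_bundle(out / "refined_sua" / s.slide_id, res.refined_pmap, mask=s.gt)
            n_corr = _fncr_slide_counts(res, s.gt)[0] if s.has_gt else None
            update_rows.append(
                {"slide_id": s.slide_id, "provenance": "sua",
                 "n_updated": res.n_updated, "n_correct_updates": n_corr}
            )
        if run_baseline:
            mask = det.baseline_detect_fn_pixels(s.pmap, s.umap, tcfg, tau_pixel)
            res = ref.refine_baseline(s.pmap, mask, tcfg)
            base_results[s.slide_id] = res
            write_slide_bundle(out / "refined_baseline" / s.slide_id, res.refined_pmap, mask=s.gt)
            n_corr = _fncr_slide_counts(res, s.gt)[0] if s.has_gt else None
            update_rows.append(
                {"slide_id": s.slide_id, "provenance": "baseline",
                 "n_updated": res.n_updated, "n_correct_updates": n_corr}
            )
    log.append(
        f"refined {len(test)} test slides "
        f"(sua updates: {sum(r.n_updated for r in sua_results.values())}, "
        f"baseline updates: {sum(r.n_updated for r in base_results.values())})"
    )

    # --- evaluate -------------------------------------------------------
    metrics: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_slides": len(slides),
        "n_validation": len(val),
        "n_test": len(test),
        "tau": tau,
        "tau_pixel": tau_pixel,
        "mode": cfg.mode,
    }
    if any_gt:
        metrics.update(_evaluate(cfg, tcfg, test, sua_results, base_results))
    else:
        metrics["note"] = "ground truth unavailable; truth-dependent metrics skipped"

    # --- artifacts ------------------------------------------------------
    regions_dataframe(slides).to_csv(out / "regions.csv", index=False)
    pd.DataFrame(
        update_rows, columns=["slide_id", "provenance", "n_updated", "n_correct_updates"]
    ).to_csv(out / "update_log.csv", index=False)
    (out / "calibration.json").write_text(json.dumps(calibration, indent=2, sort_keys=True))
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    resolved = dict(cfg.to_dict(), config_hash=cfg.config_hash())
    (out / "config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))
    (out / "run.log").write_text("\n".join(log) + "\n")
    return metrics


def _evaluate(
    cfg: RunConfig,
    tcfg: ThresholdConfig,
    test: Sequence[SlideData],
    sua_results: Dict[str, ref.RefinementResult],
    base_results: Dict[str, ref.RefinementResult],
) -> dict:
    metrics: dict = {}

    def boot(inputs, stat, name):
        try:
            return ev.bootstrap(
                inputs, stat, n_boot=cfg.n_boot, seed=cfg.seed, metric=name
            ).to_dict()
        except (UndefinedMetricError, SuasegError) as exc:
            return {"metric": name, "unavailable": str(exc)}

    lesions = {
        s.slide_id: measure.label(np.asarray(s.gt) != 0, connectivity=2) for s in test
    }
    dice_before = [(s.pmap.values >= tcfg.t2, s.gt) for s in test]
    metrics["dice_before"] = boot(dice_before, _mean_dice, "dice_before")
    try:
        metrics["froc_before"] = ev.froc_score(
            {s.slide_id: ev.detections_from_heatmap(s.pmap, tcfg.t2) for s in test},
            lesions,
        )
    except UndefinedMetricError as exc:
        metrics["froc_before"] = None
        metrics["froc_note"] = str(exc)

    slide_labels = [int(np.asarray(s.gt).any()) for s in test]
    try:
        metrics["roc_auc_before"] = ev.slide_roc_auc(
            [float(s.pmap.values.max()) for s in test], slide_labels
        )
    except UndefinedMetricError as exc:
        metrics["roc_auc_before"] = None
        metrics["roc_auc_note"] = str(exc)

    if sua_results:
        flags = [
            (
                np.array([bool(r.is_fn_truth) for r in s.records]),
                np.array([bool(r.is_fn_predicted) for r in s.records]),
            )
            for s in test
        ]
        metrics["fbeta_sua"] = boot(
            flags, lambda x: _pooled_region_fbeta(x, cfg.beta), "fbeta_sua"
        )
        dice_after = [
            (sua_results[s.slide_id].refined_binary.astype(bool), s.gt) for s in test
        ]
        metrics["dice_after_sua"] = boot(dice_after, _mean_dice, "dice_after_sua")
        fncr_counts = [_fncr_slide_counts(sua_results[s.slide_id], s.gt) for s in test]
        metrics["fncr_sua"] = boot(fncr_counts, _pooled_fncr, "fncr_sua")
        try:
            metrics["froc_after_sua"] = ev.froc_score(
                {
                    s.slide_id: ev.detections_from_heatmap(
                        sua_results[s.slide_id].refined_pmap, tcfg.t2
                    )
                    for s in test
                },
                lesions,
            )
        except UndefinedMetricError:
            metrics["froc_after_sua"] = None
        try:
            metrics["roc_auc_after_sua"] = ev.slide_roc_auc(
                [float(sua_results[s.slide_id].refined_pmap.values.max()) for s in test],
                slide_labels,
            )
        except UndefinedMetricError:
            metrics["roc_auc_after_sua"] = None

    if base_results:
        pix_flags = []
        for s in test:
            elig = det.eligible_pixel_mask(s.pmap, tcfg)
            truth = (np.asarray(s.gt) != 0)[elig]
            flagged = np.zeros(s.pmap.shape, dtype=bool)
            coords = base_results[s.slide_id].updated_pixels
            if coords.shape[0]:
                flagged[coords[:, 0], coords[:, 1]] = True
            pix_flags.append((truth, flagged[elig]))
        metrics["fbeta_baseline"] = boot(
            pix_flags, lambda x: _pooled_region_fbeta(x, cfg.beta), "fbeta_baseline"
        )
        dice_after = [
            (base_results[s.slide_id].refined_binary.astype(bool), s.gt) for s in test
        ]
        metrics["dice_after_baseline"] = boot(dice_after, _mean_dice, "dice_after_baseline")
        fncr_counts = [_fncr_slide_counts(base_results[s.slide_id], s.gt) for s in test]
        metrics["fncr_baseline"] = boot(fncr_counts, _pooled_fncr, "fncr_baseline")
    return metrics
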