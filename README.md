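# suaseg

Detection of **false-negative (FN) regions** in probabilistic segmentation
heatmaps — e.g. tumor-probability maps of histopathology whole-slide images —
by spatial aggregation of ensemble uncertainty, plus the pixel-wise baseline,
heatmap refinement, and a full evaluation stack (F-beta, Dice, FNCR, FROC,
ROC-AUC, slide-level bootstrap). A synthetic scene generator makes the whole
pipeline testable without any image downloads.

## Method overview

1. **Fusion** — an ensemble of per-pixel softmax maps is averaged into one
   segmentation heatmap; the binary entropy of the mean (in nats) is the
   uncertainty heatmap (`suaseg.heatmap`).
2. **NPR extraction** — *negative prediction regions* are connected
   components of pixels whose fused softmax lies strictly between a lower
   bound `t1` (default 0.55) and the positive threshold `t2` (default 0.95)
   (`suaseg.npr`).
3. **Detection** — each NPR is scored by the mean (or 90th percentile) of
   its pixels' entropies; regions scoring strictly above a threshold `tau`
   are flagged as FN regions. `tau` is calibrated on validation slides by
   maximizing F-beta (beta = 0.5). The baseline flags individual eligible
   pixels by their own entropy instead (`suaseg.detection`).
4. **Refinement** — flagged regions (or pixels) are converted to positive
   predictions with probability 1.0; refinement only ever adds positives and
   is idempotent (`suaseg.refinement`).
5. **Evaluation** — F-beta, Dice, pooled false-negative conversion rate
   (FNCR = Σ correctly-converted / Σ updated pixels), lesion-level FROC,
   slide-level ROC-AUC, each with a slide-resampling bootstrap
   (`suaseg.evaluation`).
6. **Synthetic data** — scenes with planted detected-tumor blobs,
   FN-candidate blobs (sub-threshold softmax, elevated entropy) and
   TN distractors (in-range softmax, baseline entropy); the entropy
   separation `delta` shrinks under a domain-`shift` knob
   (`suaseg.synthetic`).

## CLI

```sh
# generate a 6-slide synthetic fixture
suaseg synth --out fixtures/ --n-slides 6 --seed 3

# full pipeline: fuse -> extract -> calibrate -> detect -> refine -> evaluate
cat > run.yaml <<EOF
input_dir: fixtures
output_dir: runs/demo
mode: both          # sua | baseline | both
n_boot: 1000
seed: 7
EOF
suaseg run run.yaml
```

`runs/demo/` then contains `regions.csv` (per-NPR aggregates, truth and
predictions), `calibration.json`, refined heatmaps under `refined_sua/` and
`refined_baseline/`, `update_log.csv`, `metrics.json` and the resolved
`config.yaml` (with a config hash for reproducibility). Individual stages
are also available as `suaseg extract|calibrate|detect|refine|evaluate`;
see `suaseg <cmd> --help`.

Slide bundles are directories with a `layout.json` sidecar declaring the
raster convention: a multi-page float TIFF stack (one page per ensemble
member), per-member files, a fused single-map TIFF, or an `.npz` archive,
with ground-truth masks as binary PNG.

## Scope notes

The package starts from heatmaps: no neural-network training or inference,
no WSI pyramid handling, and no reproduction of dataset-specific headline
numbers (those require the original slide cohorts and trained ensembles).
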