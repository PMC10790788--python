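import itertools

import numpy as np
import pytest

from suaseg import (
    ConfusionCounts,
    InvalidInputError,
    ThresholdConfig,
    UndefinedMetricError,
    bootstrap,
    detections_from_heatmap,
    dice,
    f_beta,
    fncr,
    froc_score,
    refine_baseline,
    slide_roc_auc,
)

from conftest import make_pmap


class TestFBeta:
    @pytest.mark.parametrize("beta", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("tp,err", [(3, 1), (1, 1), (9, 3), (4, 0)])
    def test_equal_precision_recall_identity(self, beta, tp, err):
        # precision = recall = tp/(tp+err) -> F-beta equals that value
        x = tp / (tp + err)
        counts = ConfusionCounts(tp=tp, fp=err, fn=err)
        assert f_beta(counts, beta=beta) == pytest.approx(x)

    def test_zero_tp(self):
        assert f_beta(ConfusionCounts(tp=0, fp=3, fn=2)) == 0.0

    def test_direct_evaluation(self):
        # precision 0.8, recall 0.5: tp=4, fp=1, fn=4
        got = f_beta(ConfusionCounts(tp=4, fp=1, fn=4), beta=0.5)
        b2 = 0.25
        want = (1 + b2) * 0.8 * 0.5 / (b2 * 0.8 + 0.5)
        assert want == pytest.approx(0.714286, abs=1e-6)
        assert got == pytest.approx(want)

    def test_all_zero_undefined(self):
        with pytest.raises(UndefinedMetricError):
            f_beta(ConfusionCounts(tp=0, fp=0, fn=0))

    def test_one_iff_no_errors(self, rng):
        assert f_beta(ConfusionCounts(tp=5, fp=0, fn=0)) == 1.0
        for _ in range(20):
            tp, fp, fn = rng.integers(0, 6, size=3)
            if tp + fp + fn == 0:
                continue
            val = f_beta(ConfusionCounts(tp=int(tp), fp=int(fp), fn=int(fn)))
            assert 0.0 <= val <= 1.0
            assert (val == 1.0) == (tp > 0 and fp == 0 and fn == 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            ConfusionCounts(tp=-1, fp=0, fn=0)


class TestDice:
    def test_identical_masks(self, rng):
        m = rng.random((8, 8)) > 0.5
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, 0] = True
        b[3, 3] = True
        assert dice(a, b) == 0.0

    def test_direct_evaluation(self):
        # TP=3, FP=1, FN=1 -> 6/8
        pred = np.array([[1, 1, 1, 1, 0]], dtype=bool)
        gt = np.array([[1, 1, 1, 0, 1]], dtype=bool)
        assert dice(pred, gt) == pytest.approx(0.75)

    def test_both_empty_is_one(self):
        z = np.zeros((3, 3), dtype=bool)
        assert dice(z, z) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(InvalidInputError):
            dice(np.zeros((3, 3)), np.zeros((4, 4)))


def _refined(pmap_vals, mask):
    cfg = ThresholdConfig()
    return refine_baseline(make_pmap(np.asarray(pmap_vals, float)), mask, cfg)


class TestFncr:
    def test_all_updated_tumor_is_one(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 0:3] = True
        gt = np.ones((4, 4), dtype=np.uint8)
        res = _refined(np.full((4, 4), 0.1), mask)
        assert fncr([res], [gt]) == 1.0

    def test_no_updated_tumor_is_zero(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 0:3] = True
        gt = np.zeros((4, 4), dtype=np.uint8)
        assert fncr([_refined(np.full((4, 4), 0.1), mask)], [gt]) == 0.0

    def test_pooled_across_slides(self):
        # slide A: 4 updated, 3 tumor; slide B: 4 updated, 1 tumor -> 4/8
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, :] = True
        gt_a = np.zeros((4, 4), dtype=np.uint8)
        gt_a[0, 0:3] = 1
        gt_b = np.zeros((4, 4), dtype=np.uint8)
        gt_b[0, 0] = 1
        results = [_refined(np.full((4, 4), 0.1), mask) for _ in range(2)]
        assert fncr(results, [gt_a, gt_b]) == pytest.approx(0.5)
        # pooled value lies between per-slide ratios
        assert 1 / 4 <= 0.5 <= 3 / 4

    def test_no_updates_undefined(self):
        res = _refined(np.full((4, 4), 0.1), np.zeros((4, 4), dtype=bool))
        with pytest.raises(UndefinedMetricError):
            fncr([res], [np.zeros((4, 4), dtype=np.uint8)])


def lesion_map(*boxes, shape=(8, 8)):
    out = np.zeros(shape, dtype=int)
    for i, (r0, r1, c0, c1) in enumerate(boxes, start=1):
        out[r0:r1, c0:c1] = i
    return out


class TestFroc:
    def test_perfect_detector(self):
        lesions = {"a": lesion_map((0, 2, 0, 2))}
        dets = {"a": [(0, 0, 1.0)]}
        assert froc_score(dets, lesions) == 1.0

    def test_no_detections(self):
        lesions = {"a": lesion_map((0, 2, 0, 2))}
        assert froc_score({"a": []}, lesions) == 0.0

    def test_three_slide_hand_oracle(self):
        # slides a, b have one lesion each; c has none. Confidences are laid
        # out so the curve, enumerated by hand over the 5 thresholds, is
        #   fps: 0, 1/3, 2/3, 1   sens: 1/2, 1/2, 1, 1
        # interpolated at {0.25,0.5,1,2,4,8}: 0.5, 0.75, 1, 1, 1, 1 -> 0.875
        lesions = {
            "a": lesion_map((0, 2, 0, 2)),
            "b": lesion_map((0, 2, 0, 2)),
            "c": lesion_map(),
        }
        dets = {
            "a": [(0, 0, 0.9), (5, 5, 0.85)],
            "b": [(0, 0, 0.75), (5, 5, 0.8)],
            "c": [(3, 3, 0.7)],
        }
        assert froc_score(dets, lesions) == pytest.approx(0.875)

    def test_slide_order_invariant(self):
        lesions = {"a": lesion_map((0, 2, 0, 2)), "b": lesion_map((2, 4, 2, 4))}
        dets = {"a": [(0, 0, 0.9), (6, 6, 0.4)], "b": [(2, 2, 0.7)]}
        s1 = froc_score(dets, lesions)
        s2 = froc_score(dict(reversed(list(dets.items()))), lesions)
        assert s1 == s2

    def test_no_lesions_undefined(self):
        with pytest.raises(UndefinedMetricError):
            froc_score({"a": [(0, 0, 1.0)]}, {"a": lesion_map()})

    def test_detections_from_heatmap(self):
        vals = np.full((8, 8), 0.1)
        vals[0:2, 0:2] = [[0.96, 0.97], [0.95, 0.96]]
        vals[5, 5] = 0.99
        dets = detections_from_heatmap(make_pmap(vals), 0.95)
        assert len(dets) == 2
        assert (0, 1, pytest.approx(0.97)) in [(r, c, v) for r, c, v in dets]
        assert (5, 5, pytest.approx(0.99)) in [(r, c, v) for r, c, v in dets]


class TestSlideRocAuc:
    def test_perfect_separation(self):
        assert slide_roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_tied_is_half(self):
        assert slide_roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_matches_mann_whitney_oracle(self, rng):
        for _ in range(10):
            scores = rng.random(12)
            labels = (rng.random(12) > 0.5).astype(int)
            if labels.sum() in (0, 12):
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            pairs = [(p, n) for p in pos for n in neg]
            want = np.mean([1.0 if p > n else 0.5 if p == n else 0.0 for p, n in pairs])
            assert slide_roc_auc(scores, labels) == pytest.approx(want)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            slide_roc_auc([0.1, 0.2], [1, 1])


class TestBootstrap:
    def test_constant_metric_zero_sd(self):
        rep = bootstrap([1.0, 1.0, 1.0], statistic=lambda xs: float(np.mean(xs)), n_boot=50, seed=1)
        assert rep.boot_sd == 0.0 and rep.boot_mean == 1.0

    def test_same_seed_identical(self):
        args = dict(statistic=lambda xs: float(np.max(xs)), n_boot=200, seed=9)
        a = bootstrap([1.0, 2.0, 4.0], **args)
        b = bootstrap([1.0, 2.0, 4.0], **args)
        assert a == b

    def test_matches_exhaustive_enumeration(self):
        # E[max of a 3-resample] over all 27 equally likely resamples
        vals = [1.0, 2.0, 4.0]
        exhaustive = np.mean([max(t) for t in itertools.product(vals, repeat=3)])
        rep = bootstrap(vals, statistic=lambda xs: float(np.max(xs)), n_boot=20000, seed=3)
        assert rep.boot_mean == pytest.approx(exhaustive, abs=0.05)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            bootstrap([], statistic=lambda xs: 0.0)

    def test_undefined_resamples_skipped(self):
        def stat(xs):
            if all(x == 0 for x in xs):
                raise UndefinedMetricError("empty")
            return float(np.mean(xs))

        rep = bootstrap([0.0, 1.0], statistic=stat, n_boot=200, seed=0)
        assert rep.boot_mean > 0.0
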