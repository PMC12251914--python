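"""Detection metrics: matching, PR/AP integration, mAP and P/R/F1."""

import numpy as np
import pytest

from yolo_ifsc.metrics import (ConfusionCounts, compute_map, compute_pr_ap,
                               evaluate, match_detections, precision_recall_f1)
from yolo_ifsc.network import Detection, box_iou


def _d(cid, cx, cy, w, h, conf=1.0):
    return Detection(cid, (cx, cy, w, h), conf)


class TestMatching:
    def test_single_true_positive(self):
        gt = [_d(0, 0.5, 0.5, 0.2, 0.2)]
        pred = [_d(0, 0.52, 0.5, 0.2, 0.2, 0.9)]
        assert box_iou(pred[0].xyxy(), gt[0].xyxy()) > 0.5
        cc = match_detections(pred, gt)[0]
        assert (cc.tp, cc.fp, cc.fn) == (1, 0, 0)

    def test_one_to_one_matching_makes_second_overlap_a_fp(self):
        gt = [_d(0, 0.5, 0.5, 0.2, 0.2)]
        pred = [_d(0, 0.5, 0.5, 0.2, 0.2, 0.9), _d(0, 0.51, 0.5, 0.2, 0.2, 0.8)]
        cc = match_detections(pred, gt)[0]
        assert (cc.tp, cc.fp, cc.fn) == (1, 1, 0)

    def test_wrong_class_never_matches(self):
        gt = [_d(1, 0.5, 0.5, 0.2, 0.2)]
        pred = [_d(0, 0.5, 0.5, 0.2, 0.2, 0.9)]
        counts = match_detections(pred, gt)
        assert counts[0].fp == 1 and counts[1].fn == 1

    def test_greedy_rule_equals_brute_force_on_random_cases(self):
        """5 predictions vs 3 ground truths: the greedy confidence-ordered,
        best-IoU assignment must equal an independent step-by-step oracle."""
        rng = np.random.default_rng(12)
        for _ in range(20):
            gts = [_d(0, *rng.uniform(0.25, 0.75, 2), *rng.uniform(0.1, 0.3, 2))
                   for _ in range(3)]
            preds = [_d(0, *rng.uniform(0.25, 0.75, 2), *rng.uniform(0.1, 0.3, 2),
                        float(rng.uniform(0.1, 1.0))) for _ in range(5)]
            # oracle: explicit re-simulation of the documented rule
            order = sorted(range(5), key=lambda i: (-preds[i].confidence, i))
            taken = set()
            tp = 0
            for i in order:
                cands = [(box_iou(preds[i].xyxy(), g.xyxy()), j)
                         for j, g in enumerate(gts) if j not in taken]
                cands = [(iou, j) for iou, j in cands if iou >= 0.5]
                if cands:
                    best = max(cands, key=lambda t: (t[0], -t[1]))
                    taken.add(best[1])
                    tp += 1
            cc = match_detections(preds, gts)[0]
            assert cc.tp == tp
            assert cc.fp == 5 - tp
            assert cc.fn == 3 - tp

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            match_detections([], [], iou_thr=0.0)


class TestAveragePrecision:
    def test_perfect_ranking_gives_ap_one(self):
        curve = compute_pr_ap([True, True, True], [0.9, 0.8, 0.7], 3)
        assert curve.ap == pytest.approx(1.0)

    def test_all_false_gives_ap_zero(self):
        curve = compute_pr_ap([False, False], [0.9, 0.8], 2)
        assert curve.ap == 0.0

    def test_tp_fp_tp_ranking_gives_five_sixths(self):
        # precision points (1, 1/2, 2/3); envelope (1, 2/3, 2/3);
        # AP = 0.5*1 + 0.5*(2/3) = 5/6
        curve = compute_pr_ap([True, False, True], [0.9, 0.8, 0.7], 2)
        assert curve.ap == pytest.approx(5 / 6)

    def test_recall_is_nondecreasing_along_the_sweep(self):
        rng = np.random.default_rng(5)
        flags = rng.uniform(size=30) < 0.5
        curve = compute_pr_ap(flags, rng.uniform(size=30), int(flags.sum()) + 2)
        assert np.all(np.diff(curve.recall) >= 0)
        assert 0.0 <= curve.ap <= 1.0

    def test_envelope_area_matches_fine_grid_integration(self):
        """Independent oracle: rasterise the precision envelope on a 1e-5
        recall grid and integrate numerically."""
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = int(rng.integers(2, 15))
            n_gt = int(rng.integers(1, 8))
            flags = rng.uniform(size=n) < 0.6
            confs = rng.uniform(size=n)
            curve = compute_pr_ap(flags, confs, max(n_gt, 1))
            order = np.argsort(-confs, kind="stable")
            tp = np.cumsum(flags[order])
            fp = np.cumsum(~flags[order])
            rec = tp / max(n_gt, 1)
            prec = tp / np.maximum(tp + fp, 1)
            env = np.maximum.accumulate(prec[::-1])[::-1]
            grid = np.arange(0.0, rec[-1], 1e-5) + 5e-6
            vals = np.zeros_like(grid)
            for g_i, r in enumerate(grid):
                k = np.searchsorted(rec, r, side="left")
                vals[g_i] = env[min(k, len(env) - 1)]
            oracle = vals.sum() * 1e-5
            assert abs(curve.ap - oracle) < 1e-4

    def test_zero_ground_truth_is_an_error(self):
        with pytest.raises(ValueError):
            compute_pr_ap([True], [0.9], 0)


class TestMapAndPRF1:
    def test_map_is_the_arithmetic_mean(self):
        assert compute_map({0: 1.0, 1: 0.5}) == pytest.approx(0.75)
        assert compute_map({3: 0.42}) == pytest.approx(0.42)
        assert compute_map({i: 0.6 for i in range(24)}) == pytest.approx(0.6)

    def test_worked_prf1_example(self):
        p, r, f1 = precision_recall_f1(ConfusionCounts(tp=8, fp=2, fn=2))
        assert (p, r, f1) == (0.8, 0.8, pytest.approx(0.8))

    def test_degenerate_zero_counts(self):
        assert precision_recall_f1(ConfusionCounts()) == (0.0, 0.0, 0.0)

    def test_f1_is_the_harmonic_mean_consistency_check(self):
        # published operating point P=0.914, R=0.841 implies F1 ~ 0.876 under
        # the harmonic-mean definition (reported F1 tables may use another
        # operating point; this is a consistency check, not an equality)
        _p, _r, f1 = precision_recall_f1(ConfusionCounts(tp=841, fp=79, fn=159))
        assert f1 == pytest.approx(2 * 0.914 * 0.841 / (0.914 + 0.841), abs=1e-3)


class TestCorpusEvaluation:
    def _corpus(self):
        gts = [[_d(0, 0.3, 0.3, 0.2, 0.2), _d(1, 0.7, 0.7, 0.2, 0.2)],
               [_d(0, 0.5, 0.5, 0.3, 0.3)]]
        preds = [[_d(0, 0.3, 0.3, 0.2, 0.2, 0.9), _d(1, 0.7, 0.7, 0.2, 0.2, 0.8),
                  _d(1, 0.1, 0.1, 0.1, 0.1, 0.3)],
                 [_d(0, 0.5, 0.5, 0.3, 0.3, 0.95)]]
        return preds, gts

    def test_duplication_invariance(self):
        preds, gts = self._corpus()
        base = evaluate(preds, gts)
        dup = evaluate([p + p for p in preds], [g + g for g in gts])
        for c in base.per_class:
            assert dup.per_class[c]["AP"] == pytest.approx(base.per_class[c]["AP"])
        assert dup.map50 == pytest.approx(base.map50)

    def test_permutation_invariance_of_inputs(self):
        preds, gts = self._corpus()
        base = evaluate(preds, gts)
        perm = evaluate([list(reversed(p)) for p in preds], gts)
        assert perm.map50 == pytest.approx(base.map50)

    def test_missing_class_warns_and_is_excluded(self):
        preds = [[_d(5, 0.5, 0.5, 0.2, 0.2, 0.9)]]
        gts = [[]]
        with pytest.warns(UserWarning):
            rep = evaluate(preds, gts)
        assert rep.map50 == 0.0
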