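"""Evaluation metrics against hand-worked values and a brute-force oracle."""

import numpy as np
import pytest

from leaf3d.metrics import (
    average_precision,
    count_agreement,
    evaluate,
    match_instances,
    miou,
    point_metrics,
)


def brute_force_reference(pred, gt, scores=None, iou_threshold=0.5):
    """Set-based re-implementation: enumerate all group pairs explicitly."""
    pred_sets = {int(k): set(np.nonzero(pred == k)[0]) for k in np.unique(pred) if k >= 0}
    gt_sets = {int(k): set(np.nonzero(gt == k)[0]) for k in np.unique(gt) if k >= 0}
    ious = []
    for pl, ps in pred_sets.items():
        for gl, gs in gt_sets.items():
            inter = len(ps & gs)
            if inter:
                ious.append((inter / len(ps | gs), pl, gl))
    ious.sort(key=lambda t: (-t[0], t[1], t[2]))
    matching, up, ug = [], set(), set()
    for iou, pl, gl in ious:
        if pl in up or gl in ug:
            continue
        matching.append((pl, gl, iou))
        up.add(pl)
        ug.add(gl)
    tp = sum(len(pred_sets[pl] & gt_sets[gl]) for pl, gl, _ in matching)
    fp = sum(len(s) for s in pred_sets.values()) - tp
    fn = sum(len(s) for s in gt_sets.values()) - tp
    by_gt = {gl: iou for _, gl, iou in matching}
    mean_iou = sum(by_gt.get(gl, 0.0) for gl in gt_sets) / len(gt_sets) if gt_sets else None
    ap = None
    if scores is not None and gt_sets:
        ranked = sorted(pred_sets, key=lambda pl: (-scores.get(pl, 0.0), pl))
        claimed, flags = set(), []
        for pl in ranked:
            best = (0.0, None)
            for gl, gs in gt_sets.items():
                if gl in claimed:
                    continue
                inter = len(pred_sets[pl] & gs)
                iou = inter / len(pred_sets[pl] | gs)
                if iou > best[0]:
                    best = (iou, gl)
            if best[1] is not None and best[0] >= iou_threshold:
                claimed.add(best[1])
                flags.append(True)
            else:
                flags.append(False)
        ap, tp_cum, prev_r = 0.0, 0, 0.0
        for i, f in enumerate(flags, 1):
            tp_cum += f
            r = tp_cum / len(gt_sets)
            ap += (tp_cum / i) * (r - prev_r)
            prev_r = r
    return tp, fp, fn, matching, mean_iou, ap


class TestPointMetrics:
    def test_worked_example(self):
        # matched pred group of 10, 9 shared with its gt group of 12
        gt = np.array([0] * 12 + [-1] * 3)
        pred = np.concatenate([np.full(9, 4), [-1, -1, -1], [4], [-1, -1]])
        tp, fp, fn, precision, recall, f1 = point_metrics(pred, gt)
        assert (tp, fp, fn) == (9, 1, 3)
        assert precision == pytest.approx(0.9)
        assert recall == pytest.approx(0.75)
        assert f1 == pytest.approx(2 * 9 / 22)

    def test_perfect_prediction(self):
        gt = np.array([0, 0, 1, 1, 2])
        _, _, _, p, r, f1 = point_metrics(gt + 10, gt)
        assert (p, r, f1) == (1.0, 1.0, 1.0)

    def test_empty_prediction(self):
        gt = np.array([0, 0, 1])
        tp, fp, fn, p, r, f1 = point_metrics(np.full(3, -1), gt)
        assert (tp, fn, r) == (0, 3, 0.0)
        assert np.isnan(p)  # undefined-precision sentinel


class TestMatchInstances:
    def test_identity_partitions(self):
        gt = np.array([0, 0, 1, 1])
        m = match_instances(gt, gt)
        assert [(pl, gl) for pl, gl, _ in m] == [(0, 0), (1, 1)]
        assert all(iou == 1.0 for _, _, iou in m)

    def test_split_prediction_keeps_larger_half(self):
        gt = np.zeros(10, dtype=int)
        pred = np.array([1] * 7 + [2] * 3)
        m = match_instances(pred, gt)
        assert len(m) == 1
        assert m[0][0] == 1 and m[0][2] == pytest.approx(0.7)

    def test_disjoint_labelings_have_no_matches(self):
        assert match_instances(np.array([1, 1, -1]), np.array([-1, -1, 0])) == []


class TestMiou:
    def test_two_groups_average(self):
        #  gt group 0: IoU 0.8 (8/10); gt group 1: IoU 0.6 (6/10)
        gt = np.array([0] * 10 + [1] * 10)
        pred = np.concatenate([np.full(8, 5), [-1, -1], np.full(6, 6), np.full(4, -1)])
        assert miou(pred, gt) == pytest.approx((8 / 10 + 6 / 10) / 2)

    def test_no_predictions_scores_zero(self):
        assert miou(np.full(6, -1), np.array([0, 0, 0, 1, 1, 1])) == 0.0


class TestAveragePrecision:
    def test_all_correct_any_order(self):
        gt = np.array([0] * 5 + [1] * 5)
        pred = np.array([3] * 5 + [4] * 5)
        assert average_precision(pred, gt, {3: 0.1, 4: 0.9}, 0.5) == 1.0

    def test_tp_fp_tp_ranking_gives_five_sixths(self):
        # 2 gt groups; the middle-ranked prediction covers only unlabeled
        # points, so the ranked decisions are [TP, FP, TP]
        gt = np.concatenate([np.zeros(10), np.ones(10), np.full(10, -1)]).astype(int)
        pred = np.concatenate([np.zeros(10), np.full(10, 2), np.ones(10)]).astype(int)
        ap = average_precision(pred, gt, {0: 0.9, 1: 0.8, 2: 0.7}, 0.5)
        assert ap == pytest.approx(5 / 6)

    def test_all_below_threshold_scores_zero(self):
        gt = np.array([0] * 8)
        pred = np.array([1] * 2 + [-1] * 6)  # IoU 0.25 < 0.5
        assert average_precision(pred, gt, {1: 0.9}, 0.5) == 0.0

    def test_monotone_non_increasing_in_threshold(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            n = rng.integers(10, 50)
            gt = rng.integers(-1, 4, n)
            pred = rng.integers(-1, 4, n)
            scores = {int(k): float(rng.random()) for k in np.unique(pred) if k >= 0}
            if not (gt >= 0).any():
                continue
            ap50 = average_precision(pred, gt, scores, 0.5)
            ap75 = average_precision(pred, gt, scores, 0.75)
            assert ap75 <= ap50 + 1e-12

    def test_no_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            average_precision(np.array([0]), np.array([-1]), {0: 1.0}, 0.5)


class TestCountAgreement:
    def test_perfect_agreement(self):
        r2, mape, rmse = count_agreement([3, 5, 8], [3, 5, 8])
        assert (r2, mape, rmse) == (1.0, 0.0, 0.0)

    def test_worked_example(self):
        r2, mape, rmse = count_agreement([10, 20], [9, 22])
        assert mape == pytest.approx(10.0)
        assert rmse == pytest.approx(np.sqrt(2.5))

    def test_constant_mean_prediction_scores_zero_r2(self):
        y = np.array([2.0, 4.0, 6.0])
        r2, _, _ = count_agreement(y, np.full(3, y.mean()))
        assert r2 == pytest.approx(0.0)

    def test_zero_true_count_rejected(self):
        with pytest.raises(ValueError):
            count_agreement([0, 2], [1, 2])


class TestOracleEquivalence:
    def test_exact_agreement_on_random_labelings(self):
        """100 seeded random labelings of <= 50 points: exact agreement with
        the pair-enumeration oracle for TP/FP/FN, mIoU and AP."""
        rng = np.random.default_rng(99)
        checked = 0
        for _ in range(100):
            n = int(rng.integers(5, 51))
            gt = rng.integers(-1, 5, n)
            pred = rng.integers(-1, 5, n)
            if not (gt >= 0).any():
                continue
            scores = {int(k): float(rng.random()) for k in np.unique(pred) if k >= 0}
            tp_o, fp_o, fn_o, _, miou_o, ap_o = brute_force_reference(pred, gt, scores, 0.5)
            tp, fp, fn, *_ = point_metrics(pred, gt)
            assert (tp, fp, fn) == (tp_o, fp_o, fn_o)
            assert miou(pred, gt) == pytest.approx(miou_o, abs=1e-12)
            assert average_precision(pred, gt, scores, 0.5) == pytest.approx(ap_o, abs=1e-12)
            checked += 1
        assert checked >= 90

    def test_report_values_bounded(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            n = int(rng.integers(10, 40))
            gt = rng.integers(0, 3, n)
            pred = rng.integers(-1, 3, n)
            rep = evaluate(pred, gt, conf=rng.random(n))
            for val in (rep.precision, rep.recall, rep.f1, rep.miou, *rep.ap.values()):
                if not np.isnan(val):
                    assert 0.0 <= val <= 1.0
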