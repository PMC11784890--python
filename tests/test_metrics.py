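"""Evaluator correctness, including a fully independent oracle evaluator
built on shapely geometry and a from-scratch P-R sweep."""

import numpy as np
import pytest
from shapely.geometry import box as shapely_box

from cropdet.metrics import (DetectionRecord, GroundTruth, average_precision,
                             confusion_matrix, evaluate, match_detections,
                             mean_ap, precision_recall, IOU_THRESHOLDS)


# ---------------------------------------------------------------------------
# independent oracle (different geometry backend, different AP algorithm)
# ---------------------------------------------------------------------------

def shapely_iou(a, b):
    pa, pb = shapely_box(*a), shapely_box(*b)
    inter = pa.intersection(pb).area
    union = pa.union(pb).area
    return inter / union if union > 0 else 0.0


def oracle_ap(dets, gts, iou_thr):
    """Exhaustive single-class AP: greedy matching with shapely IoU, then
    101-point interpolation computed as an explicit loop."""
    n_gt = sum(len(g) for g in gts)
    if n_gt == 0:
        return float("nan")
    rows = []
    for img, (d, g) in enumerate(zip(dets, gts)):
        used = set()
        order = np.argsort(-d.scores, kind="stable")
        for i in order:
            best, best_iou = None, iou_thr
            for j in range(len(g)):
                if j in used or g.labels[j] != d.labels[i]:
                    continue
                v = shapely_iou(d.boxes[i], g.boxes[j])
                if v >= best_iou and (best is None or v > best_iou):
                    best, best_iou = j, v
            if best is not None:
                used.add(best)
                rows.append((d.scores[i], 1))
            else:
                rows.append((d.scores[i], 0))
    rows.sort(key=lambda r: -r[0])
    tps = np.cumsum([r[1] for r in rows]) if rows else np.zeros(0)
    fps = np.cumsum([1 - r[1] for r in rows]) if rows else np.zeros(0)
    rec = tps / n_gt
    prec = tps / np.maximum(tps + fps, 1)
    ap = 0.0
    for r in np.linspace(0, 1, 101):
        candidates = prec[rec >= r - 1e-12]
        ap += candidates.max() if len(candidates) else 0.0
    return ap / 101.0


def random_eval_case(rng, n_classes=3, n_images=4):
    dets, gts = [], []
    for _ in range(n_images):
        m = rng.integers(0, 6)
        gb = np.sort(rng.uniform(0, 100, size=(m, 2, 2)), axis=1).reshape(-1, 4)[:, [0, 2, 1, 3]]
        gb[:, 2:] = gb[:, :2] + np.maximum(gb[:, 2:] - gb[:, :2], 2.0)
        gl = rng.integers(0, n_classes, m)
        gts.append(GroundTruth(gb, gl))
        n = rng.integers(0, 8)
        if n and m and rng.random() < 0.7:
            # jittered copies of gt boxes plus noise detections
            pick = rng.integers(0, m, n)
            db = gb[pick] + rng.normal(0, 3, size=(n, 4))
            db = np.concatenate([np.minimum(db[:, :2], db[:, 2:]),
                                 np.maximum(db[:, :2], db[:, 2:])], axis=1)
            dl = np.where(rng.random(n) < 0.8, gl[pick], rng.integers(0, n_classes, n))
        else:
            db = np.sort(rng.uniform(0, 100, size=(n, 2, 2)), axis=1).reshape(-1, 4)[:, [0, 2, 1, 3]]
            db[:, 2:] = db[:, :2] + np.maximum(db[:, 2:] - db[:, :2], 2.0)
            dl = rng.integers(0, n_classes, n)
        dets.append(DetectionRecord(db, dl, rng.random(n)))
    return dets, gts


# ---------------------------------------------------------------------------

class TestMatching:
    def test_below_threshold_is_fp(self):
        d = DetectionRecord([[0, 0, 10, 5]], [0], [0.9])     # IoU 0.5 area ratio
        g = GroundTruth([[0, 0, 10, 10]], [0])
        res = match_detections(d, g, iou_threshold=0.6)
        assert res.tp == 0 and res.fp == 1 and res.fn == 1

    def test_greedy_duplicate_detection(self):
        g = GroundTruth([[0, 0, 10, 10]], [0])
        d = DetectionRecord([[0, 0, 10, 10], [1, 1, 11, 11]], [0, 0], [0.9, 0.8])
        res = match_detections(d, g, 0.5)
        assert list(res.det_is_tp) == [True, False]

    def test_perfect_matching(self):
        boxes = np.array([[0, 0, 5, 5], [10, 10, 20, 20], [30, 0, 40, 8]])
        labels = np.array([0, 1, 2])
        res = match_detections(DetectionRecord(boxes, labels, [0.9, 0.8, 0.7]),
                               GroundTruth(boxes, labels), 0.5)
        assert res.tp == 3 and res.fp == 0 and res.fn == 0

    def test_class_must_match(self):
        d = DetectionRecord([[0, 0, 10, 10]], [1], [0.9])
        g = GroundTruth([[0, 0, 10, 10]], [0])
        assert match_detections(d, g, 0.5).tp == 0
        assert match_detections(d, g, 0.5, class_agnostic=True).tp == 1


class TestPrecisionRecall:
    @pytest.mark.parametrize("tp,fp,fn,expected", [
        (8, 2, 0, (0.8, 1.0)), (8, 0, 2, (1.0, 0.8)), (0, 0, 0, (0.0, 0.0)),
    ])
    def test_values(self, tp, fp, fn, expected):
        assert precision_recall(tp, fp, fn) == pytest.approx(expected)


class TestAveragePrecision:
    def test_hand_examples(self):
        g = [GroundTruth([[0, 0, 10, 10]], [0])]
        assert average_precision([DetectionRecord([[0, 0, 10, 10]], [0], [0.9])], g, 0.5) == 1.0
        assert average_precision([DetectionRecord([[50, 50, 60, 60]], [0], [0.9])], g, 0.5) == 0.0
        two = [DetectionRecord([[50, 50, 60, 60], [0, 0, 10, 10]], [0, 0], [0.9, 0.8])]
        assert average_precision(two, g, 0.5) == pytest.approx(0.5, abs=1e-12)

    def test_score_rescaling_invariance(self, rng):
        dets, gts = random_eval_case(rng)
        base = average_precision(dets, gts, 0.5)
        scaled = [DetectionRecord(d.boxes, d.labels, d.scores * 7.3) for d in dets]
        assert average_precision(scaled, gts, 0.5) == pytest.approx(base, abs=1e-12)

    def test_appending_low_ranked_fp_never_increases_ap(self, rng):
        for _ in range(5):
            dets, gts = random_eval_case(rng, n_classes=1)
            base = average_precision(dets, gts, 0.5)
            worse = [DetectionRecord(np.vstack([d.boxes, [[200, 200, 210, 210]]]),
                                     np.append(d.labels, 0),
                                     np.append(d.scores, 1e-6)) for d in dets]
            assert average_precision(worse, gts, 0.5) <= base + 1e-12

    def test_covering_unmatched_gt_never_decreases_ap(self, rng):
        for _ in range(5):
            dets, gts = random_eval_case(rng, n_classes=1)
            base = average_precision(dets, gts, 0.5)
            better = [DetectionRecord(np.vstack([d.boxes, g.boxes]),
                                      np.concatenate([d.labels, g.labels]),
                                      np.concatenate([d.scores, np.full(len(g), 1e-6)]))
                      for d, g in zip(dets, gts)]
            assert average_precision(better, gts, 0.5) >= base - 1e-12

    def test_no_ground_truth_is_nan(self):
        d = [DetectionRecord([[0, 0, 5, 5]], [0], [0.5])]
        assert np.isnan(average_precision(d, [GroundTruth(np.zeros((0, 4)), [])], 0.5))


class TestMeanAP:
    def test_simple_means(self):
        per_class = {0: {t: 1.0 for t in IOU_THRESHOLDS},
                     1: {t: 0.0 for t in IOU_THRESHOLDS}}
        ap50, m = mean_ap(per_class)
        assert ap50 == 0.5 and m == 0.5

    def test_equals_bruteforce_table_mean(self, rng):
        per_class = {c: {t: rng.random() for t in IOU_THRESHOLDS} for c in range(4)}
        _, m = mean_ap(per_class)
        table = np.array([[per_class[c][t] for t in IOU_THRESHOLDS] for c in range(4)])
        assert m == pytest.approx(table.mean(), abs=1e-12)


class TestAgainstOracle:
    def test_matches_independent_evaluator_on_20_random_sets(self):
        rng = np.random.default_rng(77)
        worst = 0.0
        for _ in range(20):
            dets, gts = random_eval_case(rng, n_classes=2, n_images=3)
            for c in range(2):
                dc = [DetectionRecord(d.boxes[d.labels == c], d.labels[d.labels == c],
                                      d.scores[d.labels == c]) for d in dets]
                gc = [GroundTruth(g.boxes[g.labels == c], g.labels[g.labels == c])
                      for g in gts]
                if sum(len(g) for g in gc) == 0:
                    continue
                for thr in (0.5, 0.75):
                    mine = average_precision(dc, gc, thr)
                    ref = oracle_ap(dc, gc, thr)
                    worst = max(worst, abs(mine - ref))
        assert worst <= 1e-4


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        boxes = np.array([[0, 0, 10, 10], [20, 20, 30, 30]])
        d = [DetectionRecord(boxes, [0, 1], [0.9, 0.9])]
        g = [GroundTruth(boxes, [0, 1])]
        cm = confusion_matrix(d, g, 2)
        assert np.array_equal(cm, np.diag([1, 1, 0]))

    def test_low_scores_push_gt_to_background(self):
        boxes = np.array([[0, 0, 10, 10]])
        d = [DetectionRecord(boxes, [0], [0.1])]
        g = [GroundTruth(boxes, [0])]
        cm = confusion_matrix(d, g, 2, score_threshold=0.25)
        assert cm[0, 2] == 1 and cm.sum() == 1

    def test_row_sums_conserve_gt_counts(self, rng):
        dets, gts = random_eval_case(rng, n_classes=3)
        cm = confusion_matrix(dets, gts, 3, score_threshold=0.0)
        for c in range(3):
            expected = sum((g.labels == c).sum() for g in gts)
            assert cm[c, :].sum() == expected

    def test_misclassification_lands_off_diagonal(self):
        boxes = np.array([[0, 0, 10, 10]])
        cm = confusion_matrix([DetectionRecord(boxes, [1], [0.9])],
                              [GroundTruth(boxes, [0])], 2)
        assert cm[0, 1] == 1


def test_full_evaluate_pipeline(rng):
    dets, gts = random_eval_case(rng, n_classes=3, n_images=5)
    res = evaluate(dets, gts, 3)
    assert 0.0 <= res.ap50 <= 1.0 and 0.0 <= res.map <= 1.0
    assert res.map <= res.ap50 + 1e-9
    assert res.confusion.shape == (4, 4)
    d = res.as_dict()
    assert set(d) >= {"AP50", "mAP", "precision", "recall"}
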