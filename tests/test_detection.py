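"""Object-level evaluation: matching, precision/recall/F1, 11-point AP."""

import itertools
import math

import numpy as np
import pytest

from silagekps import (
    Box,
    ImageRecord,
    Instance,
    Polygon,
    ValidationError,
    average_precision,
    evaluate_dataset,
    match_detections,
    precision_recall_f1,
)
from silagekps.detection import MatchResult, _iou_matrix


def box_inst(x, y, w, h, score=None):
    return Instance(box=Box(x, y, x + w, y + h), score=score)


def exhaustive_max_tp(gt, det, thr=0.5):
    """Oracle: max TP count over all one-to-one assignments, ties broken
    by total IoU."""
    ious = _iou_matrix(gt, det, "box")
    best = (0, 0.0)
    for k in range(min(len(gt), len(det)) + 1):
        for gsub in itertools.permutations(range(len(gt)), k):
            for dsub in itertools.combinations(range(len(det)), k):
                tp, tot, ok = 0, 0.0, True
                for g, d in zip(gsub, dsub):
                    if ious[g, d] >= thr:
                        tp += 1
                        tot += ious[g, d]
                    else:
                        ok = False
                        break
                if ok and (tp, tot) > best:
                    best = (tp, tot)
    return best[0]


class TestMatching:
    def test_single_pair_above_threshold(self):
        gt = [box_inst(0, 0, 10, 10)]
        det = [box_inst(0, 0, 10, 15, score=0.9)]  # IoU 2/3
        m = match_detections(gt, det)
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_duplicate_detection_is_false_positive(self):
        """Two detections over one annotation: the better-localised one
        is the TP, the surplus one an FP."""
        gt = [box_inst(0, 0, 10, 10)]
        det = [
            box_inst(0, 0, 10, 12, score=0.8),  # IoU 10/12
            box_inst(0, 0, 10, 16, score=0.9),  # IoU 10/16, higher score
        ]
        m = match_detections(gt, det)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)
        # the higher-scored det sweeps first and claims the annotation
        assert m.tp_pairs[0][1] == 1
        assert m.fp_det_ids == [0]

    def test_below_threshold_is_fp_and_fn(self):
        gt = [box_inst(0, 0, 10, 10)]
        det = [box_inst(6, 0, 10, 10, score=0.9)]  # IoU 4/16 = 0.25
        m = match_detections(gt, det)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_each_side_matched_at_most_once(self):
        rng = np.random.default_rng(1)
        gt = [box_inst(*rng.uniform(0, 50, 2), 20, 20) for _ in range(4)]
        det = [box_inst(*rng.uniform(0, 50, 2), 20, 20, score=float(rng.uniform())) for _ in range(5)]
        m = match_detections(gt, det)
        gts = [g for g, _, _ in m.tp_pairs]
        dets = [d for _, d, _ in m.tp_pairs]
        assert len(set(gts)) == len(gts) and len(set(dets)) == len(dets)
        assert m.tp + m.fn == len(gt)
        assert m.tp + m.fp == len(det)
        assert all(iou >= m.iou_threshold for _, _, iou in m.tp_pairs)

    def test_raising_iou_threshold_never_adds_tp(self):
        rng = np.random.default_rng(2)
        gt = [box_inst(*rng.uniform(0, 60, 2), 25, 25) for _ in range(5)]
        det = [box_inst(*rng.uniform(0, 60, 2), 25, 25, score=float(rng.uniform())) for _ in range(5)]
        tps = [match_detections(gt, det, iou_threshold=t).tp for t in (0.3, 0.5, 0.7, 0.9)]
        assert tps == sorted(tps, reverse=True)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_exhaustive_assignment_on_small_cases(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(100):
            ng, nd = rng.integers(0, 5), rng.integers(0, 5)
            gt = [box_inst(*rng.uniform(0, 80, 2), *rng.uniform(8, 30, 2)) for _ in range(ng)]
            det = [
                box_inst(*rng.uniform(0, 80, 2), *rng.uniform(8, 30, 2), score=float(rng.uniform()))
                for _ in range(nd)
            ]
            assert match_detections(gt, det).tp == exhaustive_max_tp(gt, det)

    def test_mask_mode_requires_polygons(self):
        gt = [box_inst(0, 0, 10, 10)]
        det = [box_inst(0, 0, 10, 10, score=0.9)]
        with pytest.raises(ValidationError):
            match_detections(gt, det, mode="mask")


class TestPrecisionRecallF1:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [
            (5, 0, 0, (100.0, 100.0, 100.0)),
            (3, 1, 2, (75.0, 60.0, 200 / 3)),
            (0, 0, 3, (0.0, 0.0, 0.0)),
        ],
    )
    def test_hand_arithmetic(self, tp, fp, fn, expected):
        m = MatchResult(
            tp_pairs=[(i, i, 1.0) for i in range(tp)],
            fp_det_ids=list(range(fp)),
            fn_gt_ids=list(range(fn)),
            iou_threshold=0.5,
        )
        p, r, f1 = precision_recall_f1(m)
        assert p == pytest.approx(expected[0])
        assert r == pytest.approx(expected[1])
        assert f1 == pytest.approx(expected[2])

    def test_no_ground_truth_recall_undefined(self):
        m = MatchResult(tp_pairs=[], fp_det_ids=[0], fn_gt_ids=[], iou_threshold=0.5)
        p, r, f1 = precision_recall_f1(m)
        assert p == 0.0 and math.isnan(r)


class TestAveragePrecision:
    def test_perfect_detector_is_100(self):
        gt = {1: [box_inst(0, 0, 10, 10), box_inst(30, 30, 10, 10)]}
        det = {1: [box_inst(0, 0, 10, 10, 0.9), box_inst(30, 30, 10, 10, 0.8)]}
        assert average_precision(gt, det) == pytest.approx(100.0)

    def test_nothing_localised_is_0(self):
        gt = {1: [box_inst(0, 0, 10, 10)]}
        det = {1: [box_inst(50, 50, 10, 10, 0.9)]}
        assert average_precision(gt, det) == 0.0

    def test_hand_enumerated_three_gt_ranked_tp_fp_tp(self):
        """Ranked sweep TP, FP, TP over 3 annotations: interpolated
        precision is 1 up to recall 1/3, 2/3 up to 2/3, 0 above, so the
        11-point mean is 6/11."""
        gt = {1: [box_inst(0, 0, 10, 10), box_inst(30, 30, 10, 10), box_inst(60, 60, 10, 10)]}
        det = {
            1: [
                box_inst(0, 0, 10, 10, 0.9),    # TP
                box_inst(80, 0, 10, 10, 0.8),   # FP (hits nothing)
                box_inst(30, 30, 10, 10, 0.7),  # TP
            ]
        }
        assert average_precision(gt, det) == pytest.approx(100 * 6 / 11)

    def test_invariant_to_monotone_score_transform(self):
        rng = np.random.default_rng(3)
        gt = {i: [box_inst(*rng.uniform(0, 60, 2), 20, 20) for _ in range(3)] for i in range(4)}
        det = {
            i: [
                box_inst(g.box.xmin + rng.normal(0, 4), g.box.ymin + rng.normal(0, 4), 20, 20,
                         score=float(rng.uniform(0.1, 0.9)))
                for g in gts
            ]
            for i, gts in gt.items()
        }
        base = average_precision(gt, det)
        squeezed = {
            i: [Instance(box=d.box, score=d.score**3) for d in dets] for i, dets in det.items()
        }
        assert average_precision(gt, squeezed) == pytest.approx(base)

    def test_unscored_detection_rejected(self):
        gt = {1: [box_inst(0, 0, 10, 10)]}
        det = {1: [box_inst(0, 0, 10, 10)]}
        with pytest.raises(ValidationError):
            average_precision(gt, det)


class TestEvaluateDataset:
    def _records(self, instances_by_image):
        return [
            ImageRecord(image_id=i, width=200, height=200, instances=insts)
            for i, insts in instances_by_image.items()
        ]

    def test_perfect_detector_all_100(self):
        gt = {1: [box_inst(0, 0, 20, 20)], 2: [box_inst(40, 40, 30, 30)]}
        det = {
            1: [Instance(box=gt[1][0].box, score=0.9)],
            2: [Instance(box=gt[2][0].box, score=0.9)],
        }
        rep = evaluate_dataset(self._records(gt), self._records(det))
        assert rep.precision == 100.0 and rep.recall == 100.0
        assert rep.f1 == 100.0 and rep.ap == pytest.approx(100.0)

    def test_box_and_mask_identical_on_rectangles(self):
        sq = [(10, 10), (60, 10), (60, 40), (10, 40)]
        gt = {1: [Instance(polygon=Polygon(sq))]}
        det = {1: [Instance(polygon=Polygon(sq), score=0.9)]}
        rb = evaluate_dataset(self._records(gt), self._records(det), mode="box")
        rm = evaluate_dataset(self._records(gt), self._records(det), mode="mask")
        assert (rb.tp, rb.fp, rb.fn) == (rm.tp, rm.fp, rm.fn)
        assert rb.ap == pytest.approx(rm.ap)

    def test_empty_annotations_flagged(self):
        det = {1: [box_inst(0, 0, 10, 10, 0.9)]}
        rep = evaluate_dataset(self._records({1: []}), self._records(det))
        assert not rep.recall_defined
        assert rep.ap == 0.0

    def test_score_threshold_filters_prf_counts(self):
        gt = {1: [box_inst(0, 0, 20, 20)]}
        det = {1: [box_inst(0, 0, 20, 20, score=0.3), box_inst(100, 100, 20, 20, score=0.2)]}
        rep = evaluate_dataset(self._records(gt), self._records(det), score_threshold=0.25)
        assert (rep.tp, rep.fp, rep.fn) == (1, 0, 0)
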