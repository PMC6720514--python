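"""Object-level evaluation of kernel detections against annotations.

A detection counts as a true positive when it overlaps an annotation with
intersection-over-union at or above the threshold (0.5 by default) and
that annotation has not already been claimed by a higher-ranked
detection; every annotation can be matched at most once, and surplus
detections above the threshold are false positives.  From the matched
counts the module derives precision, recall, F1 and the 11-point
interpolated average precision of the PASCAL VOC tradition:

    AP = (1/11) * sum_{r in {0, 0.1, ..., 1}} max_{r~ >= r} p(r~)

where p(r~) is the precision observed at recall r~ along the ranked
detection sweep.  All figures are reported as percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .annotations import ImageRecord, Instance, ValidationError
from .geometry import UndefinedIoUError, box_iou, mask_iou

__all__ = [
    "MatchResult",
    "MetricsReport",
    "instance_iou",
    "match_detections",
    "precision_recall_f1",
    "average_precision",
    "evaluate_dataset",
]

Mode = Literal["box", "mask"]

RECALL_LEVELS = np.linspace(0.0, 1.0, 11)


@dataclass
class MatchResult:
    """TP/FP/FN assignment of detections to ground truth at one IoU
    threshold.  Ids are positional indices into the input lists."""

    tp_pairs: list[tuple[int, int, float]]  # (gt_id, det_id, iou)
    fp_det_ids: list[int]
    fn_gt_ids: list[int]
    iou_threshold: float

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)

    @property
    def fp(self) -> int:
        return len(self.fp_det_ids)

    @property
    def fn(self) -> int:
        return len(self.fn_gt_ids)


@dataclass
class MetricsReport:
    """Dataset-level detection metrics, all as percentages in [0, 100].

    ``recall`` is ``nan`` (and ``recall_defined`` False) when there are
    no ground-truth instances at all.
    """

    precision: float
    recall: float
    f1: float
    ap: float
    tp: int
    fp: int
    fn: int
    mode: Mode
    iou_threshold: float = 0.5
    score_threshold: float | None = None
    recall_defined: bool = True


def instance_iou(gt: Instance, det: Instance, mode: Mode) -> float:
    """IoU between two instances, on boxes or rasterised polygon masks."""
    if mode == "box":
        try:
            return box_iou(gt.box, det.box)
        except UndefinedIoUError:
            return 0.0
    if mode == "mask":
        if gt.polygon is None or det.polygon is None:
            raise ValidationError("mask-mode IoU requires polygons on both instances")
        return mask_iou(gt.polygon, det.polygon)
    raise ValueError(f"unknown mode {mode!r}")


def _iou_matrix(gt: Sequence[Instance], det: Sequence[Instance], mode: Mode) -> np.ndarray:
    m = np.zeros((len(gt), len(det)))
    for i, g in enumerate(gt):
        for j, d in enumerate(det):
            m[i, j] = instance_iou(g, d, mode)
    return m


def _det_order(det: Sequence[Instance], ious: np.ndarray) -> list[int]:
    """Descending score; score ties broken by higher best-IoU, then by
    stable input order.  Unscored detections keep input order."""
    if any(d.score is None for d in det):
        if any(d.score is not None for d in det):
            raise ValidationError("mixing scored and unscored detections")
        return list(range(len(det)))
    best = ious.max(axis=0) if ious.size else np.zeros(len(det))
    return sorted(range(len(det)), key=lambda j: (-det[j].score, -best[j], j))


def match_detections(
    gt: Sequence[Instance],
    det: Sequence[Instance],
    iou_threshold: float = 0.5,
    mode: Mode = "box",
) -> MatchResult:
    """Greedily assign detections to ground truth within one image.

    Detections are processed in descending score order; each is matched
    to the so-far-unmatched ground truth with the highest IoU when that
    IoU reaches the threshold, otherwise it is a false positive.
    Ground-truth instances left unmatched are false negatives.
    """
    ious = _iou_matrix(gt, det, mode)
    matched_gt: set[int] = set()
    tp_pairs: list[tuple[int, int, float]] = []
    fp: list[int] = []
    for j in _det_order(det, ious):
        best_i, best_iou = -1, 0.0
        for i in range(len(gt)):
            if i in matched_gt:
                continue
            if ious[i, j] > best_iou:
                best_i, best_iou = i, ious[i, j]
        if best_i >= 0 and best_iou >= iou_threshold:
            matched_gt.add(best_i)
            tp_pairs.append((best_i, j, best_iou))
        else:
            fp.append(j)
    fn = [i for i in range(len(gt)) if i not in matched_gt]
    return MatchResult(tp_pairs=tp_pairs, fp_det_ids=fp, fn_gt_ids=fn,
                       iou_threshold=iou_threshold)


def precision_recall_f1(m: MatchResult) -> tuple[float, float, float]:
    """Precision, recall and F1 as percentages.

    Degenerate conventions: precision is 0 when no detections were made;
    recall is ``nan`` when there is no ground truth at all.
    """
    tp, fp, fn = m.tp, m.fp, m.fn
    precision = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    recall = 100.0 * tp / (tp + fn) if tp + fn else math.nan
    f1 = 100.0 * 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return precision, recall, f1


def average_precision(
    gt_by_image: Mapping,
    det_by_image: Mapping,
    iou_threshold: float = 0.5,
    mode: Mode = "box",
) -> float:
    """11-point interpolated average precision (percentage).

    Detections are pooled across the dataset and swept in descending
    score order; the matching rule is applied within each image as the
    sweep descends, building the precision-recall curve whose
    interpolated precision is averaged at recall 0, 0.1, ..., 1.
    """
    n_gt = sum(len(g) for g in gt_by_image.values())
    pooled: list[tuple[float, object, int]] = []
    for image_id, dets in det_by_image.items():
        for j, d in enumerate(dets):
            if d.score is None:
                raise ValidationError(f"image {image_id}: unscored detection in AP sweep")
            pooled.append((d.score, image_id, j))
    if n_gt == 0 or not pooled:
        return 0.0

    ious = {
        image_id: _iou_matrix(gt_by_image.get(image_id, []), dets, mode)
        for image_id, dets in det_by_image.items()
    }
    # rank: descending score, ties by higher best-IoU then input order
    def rank_key(entry):
        score, image_id, j = entry
        mat = ious[image_id]
        best = mat[:, j].max() if mat.size else 0.0
        return (-score, -best, str(image_id), j)

    pooled.sort(key=rank_key)

    matched: dict = {image_id: set() for image_id in det_by_image}
    tps = np.zeros(len(pooled), dtype=bool)
    for k, (_, image_id, j) in enumerate(pooled):
        mat = ious[image_id]
        best_i, best_iou = -1, 0.0
        for i in range(mat.shape[0]):
            if i in matched[image_id]:
                continue
            if mat[i, j] > best_iou:
                best_i, best_iou = i, mat[i, j]
        if best_i >= 0 and best_iou >= iou_threshold:
            matched[image_id].add(best_i)
            tps[k] = True

    tp_cum = np.cumsum(tps)
    precision = tp_cum / np.arange(1, len(pooled) + 1)
    recall = tp_cum / n_gt
    interp = np.array(
        [precision[recall >= r].max() if np.any(recall >= r) else 0.0 for r in RECALL_LEVELS]
    )
    return float(100.0 * interp.mean())


def evaluate_dataset(
    annotations: Sequence[ImageRecord],
    detections: Sequence[ImageRecord],
    mode: Mode = "box",
    iou_threshold: float = 0.5,
    score_threshold: float | None = None,
) -> MetricsReport:
    """Evaluate a detection set against an annotation set image-by-image.

    Precision/recall/F1 use every detection at or above
    ``score_threshold`` (all detections when ``None``); AP always uses
    the full ranked sweep.  Images are paired by ``image_id``; a
    detection image absent from the annotations counts all its
    detections as false positives.
    """
    gt_by_image = {rec.image_id: rec.instances for rec in annotations}
    det_by_image = {rec.image_id: rec.instances for rec in detections}
    for image_id in det_by_image:
        gt_by_image.setdefault(image_id, [])
    for image_id in gt_by_image:
        det_by_image.setdefault(image_id, [])

    tp = fp = fn = 0
    for image_id, gts in gt_by_image.items():
        dets = det_by_image[image_id]
        if score_threshold is not None:
            dets = [d for d in dets if d.score is not None and d.score >= score_threshold]
        m = match_detections(gts, dets, iou_threshold=iou_threshold, mode=mode)
        tp += m.tp
        fp += m.fp
        fn += m.fn

    pooled = MatchResult(
        tp_pairs=[(0, 0, 1.0)] * tp, fp_det_ids=[-1] * fp, fn_gt_ids=[-1] * fn,
        iou_threshold=iou_threshold,
    )
    precision, recall, f1 = precision_recall_f1(pooled)
    have_scores = any(d.score is not None for dets in det_by_image.values() for d in dets)
    ap = (
        average_precision(gt_by_image, det_by_image, iou_threshold=iou_threshold, mode=mode)
        if have_scores
        else math.nan
    )
    return MetricsReport(
        precision=precision, recall=recall, f1=f1, ap=ap,
        tp=tp, fp=fp, fn=fn, mode=mode, iou_threshold=iou_threshold,
        score_threshold=score_threshold, recall_defined=not math.isnan(recall),
    )
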