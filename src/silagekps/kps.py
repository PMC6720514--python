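"""Kernel Processing Score (KPS) computation.

KPS is the percentage of kernel fragments whose minor-axis size falls
strictly below 4.75 mm — the sieve aperture of the laboratory Corn
Silage Processing Score.  Fragment size is the shorter side of the
minimum-area rotated rectangle around the fragment outline
(``rotated_minor``), or, for box-only detectors that cannot localise at
pixel level, the shorter side of the axis-aligned box
(``aabb_shortest``).  A fragment measuring exactly 4.75 mm counts as NOT
processed: the score uses a strict ``<``.

KPS is reported per sequence — all images captured at one processor-gap
setting — by pooling the instances of the whole sequence before taking
the percentage, so images with more fragments weigh proportionally more.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import Instance, SequenceRecord, ValidationError
from .geometry import Scale, min_area_rect, px_to_mm

__all__ = [
    "UndefinedKpsError",
    "SizeMode",
    "KpsResult",
    "instance_size_mm",
    "kps",
    "sequence_kps",
    "kps_table",
    "average_absolute_error",
    "KPS_THRESHOLD_MM",
]

KPS_THRESHOLD_MM = 4.75
DEFAULT_SCORE_THRESHOLD = 0.5


class UndefinedKpsError(ValueError):
    """Raised when a KPS is requested over zero instances; the caller
    must flag the sequence rather than silently score it 0."""


class SizeMode(str, enum.Enum):
    """How an instance's sieve-relevant size is measured."""

    ROTATED_MINOR = "rotated_minor"   # minor axis of the min-area rotated rect
    AABB_SHORTEST = "aabb_shortest"   # shortest side of the axis-aligned box


@dataclass(frozen=True)
class KpsResult:
    """A KPS value with the counts behind it, for auditability."""

    kps_percent: float
    n_below: int
    n_total: int
    threshold_mm: float
    size_mode: SizeMode

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise UndefinedKpsError("KPS over zero instances is undefined")


def instance_size_mm(inst: Instance, mode: SizeMode, s: Scale | None = None) -> float:
    """Sieve-relevant size of one instance in millimetres."""
    mode = SizeMode(mode)
    if mode is SizeMode.ROTATED_MINOR:
        if inst.polygon is None:
            raise ValidationError("rotated_minor sizing requires a polygon")
        return px_to_mm(min_area_rect(inst.polygon).minor_axis, s)
    return px_to_mm(inst.box.shortest_side, s)


def kps(
    instances: Sequence[Instance],
    mode: SizeMode,
    s: Scale | None = None,
    threshold_mm: float = KPS_THRESHOLD_MM,
    score_threshold: float | None = None,
) -> KpsResult:
    """KPS of an instance collection: 100 * |{size < threshold}| / n.

    ``score_threshold`` drops detections below the given confidence
    before scoring (annotations, which carry no score, always pass).
    """
    if score_threshold is not None:
        instances = [
            i for i in instances if i.score is None or i.score >= score_threshold
        ]
    if not instances:
        raise UndefinedKpsError("no instances left to score")
    sizes = np.array([instance_size_mm(i, mode, s) for i in instances])
    n_below = int((sizes < threshold_mm).sum())
    return KpsResult(
        kps_percent=100.0 * n_below / len(sizes),
        n_below=n_below,
        n_total=len(sizes),
        threshold_mm=threshold_mm,
        size_mode=SizeMode(mode),
    )


def sequence_kps(
    seq: SequenceRecord,
    detections_by_model: Mapping[str, Mapping],
    mode_by_model: Mapping[str, SizeMode],
    s: Scale | None = None,
    annotation_mode: SizeMode = SizeMode.ROTATED_MINOR,
    threshold_mm: float = KPS_THRESHOLD_MM,
    score_threshold: float | None = DEFAULT_SCORE_THRESHOLD,
) -> dict:
    """One KPS-table row for a processor-gap sequence.

    ``detections_by_model`` maps a model name to a mapping
    ``image_id -> list[Instance]``; instances are pooled over all images
    of the sequence before the percentage is taken.  A model with zero
    pooled instances yields ``nan`` for its cell (flagged, not 0).
    """
    row: dict = {"sequence_id": seq.sequence_id, "pg": seq.pg}
    ann_pool = [inst for im in seq.images for inst in im.instances]
    scale = s if s is not None else seq.images[0].scale
    for model, by_image in detections_by_model.items():
        pool = [inst for im in seq.images for inst in by_image.get(im.image_id, [])]
        try:
            row[model] = kps(
                pool, mode_by_model[model], scale,
                threshold_mm=threshold_mm, score_threshold=score_threshold,
            ).kps_percent
        except UndefinedKpsError:
            row[model] = math.nan
    row["annotation"] = kps(
        ann_pool, annotation_mode, scale, threshold_mm=threshold_mm
    ).kps_percent
    return row


def kps_table(
    sequences: Sequence[SequenceRecord],
    detections_by_model: Mapping[str, Mapping],
    mode_by_model: Mapping[str, SizeMode],
    **kwargs,
) -> pd.DataFrame:
    """KPS table: one row per sequence, one column per model plus the
    annotation column (the shape of the published per-PG score table)."""
    rows = [
        sequence_kps(seq, detections_by_model, mode_by_model, **kwargs)
        for seq in sequences
    ]
    return pd.DataFrame(rows)


def average_absolute_error(
    model_kps: Sequence[float], annotation_kps: Sequence[float]
) -> float:
    """Mean |model - annotation| over paired sequences, in percentage
    points — the summary row of the per-PG KPS table."""
    a = np.asarray(model_kps, dtype=float)
    b = np.asarray(annotation_kps, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValidationError("KPS columns must be equal-length 1-d vectors")
    return float(np.mean(np.abs(a - b)))
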