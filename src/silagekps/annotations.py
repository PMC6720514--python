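"""Reading, writing and splitting kernel-fragment instance datasets.

The interchange format is COCO-style JSON: an ``images`` array, an
``annotations`` array with polygon ``segmentation`` and/or ``bbox``
entries, and a single ``kernel`` category.  Boxes on disk use the COCO
``[x, y, w, h]`` dialect; in memory they are corner-based
(:class:`~silagekps.geometry.Box`), which the round-trip tests pin down.

Per-image custom fields carry the acquisition metadata this analysis
needs: ``px_per_mm`` (camera scale), ``pg`` (processor gap in mm) and
``year`` (harvest year).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .geometry import Box, Polygon, Scale, box_from_polygon

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "Instance",
    "ImageRecord",
    "SequenceRecord",
    "read_dataset",
    "write_dataset",
    "write_report",
    "split_dataset",
]

DEFAULT_CATEGORY = "kernel"


class ValidationError(ValueError):
    """Raised when on-disk data violates the instance/image invariants."""


@dataclass
class Instance:
    """One kernel fragment: a polygon outline and/or an axis-aligned box.

    Annotations carry no score; detections carry a confidence in [0, 1].
    When only the polygon is given the box is derived from its coordinate
    extremes.  ``meta`` holds generator-side ground truth (e.g. the true
    minor axis of a synthetic fragment) and is never serialised.
    """

    polygon: Polygon | None = None
    box: Box | None = None
    score: float | None = None
    category: str = DEFAULT_CATEGORY
    meta: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.polygon is None and self.box is None:
            raise ValidationError("instance needs a polygon or a box")
        if self.box is None:
            self.box = box_from_polygon(self.polygon)
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValidationError(f"score {self.score} outside [0, 1]")


@dataclass
class ImageRecord:
    """One image with its instances and acquisition metadata."""

    image_id: int | str
    width: int
    height: int
    scale: Scale = field(default_factory=Scale)
    pg: float | None = None
    year: int | None = None
    instances: list[Instance] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValidationError(f"image {self.image_id}: non-positive size")


@dataclass
class SequenceRecord:
    """All images captured at one processor-gap setting."""

    sequence_id: int | str
    pg: float
    images: list[ImageRecord]

    def __post_init__(self) -> None:
        if not self.images:
            raise ValidationError(f"sequence {self.sequence_id} is empty")
        for im in self.images:
            if im.pg is not None and im.pg != self.pg:
                raise ValidationError(
                    f"sequence {self.sequence_id}: image {im.image_id} has pg "
                    f"{im.pg} != sequence pg {self.pg}"
                )


def _segmentation_to_polygon(seg, ann_id) -> Polygon:
    if isinstance(seg, list) and seg and isinstance(seg[0], list):
        if len(seg) != 1:
            raise ValidationError(f"annotation {ann_id}: multi-part segmentation unsupported")
        seg = seg[0]
    flat = np.asarray(seg, dtype=float)
    if flat.ndim != 1 or flat.size % 2 != 0 or flat.size < 6:
        raise ValidationError(f"annotation {ann_id}: polygon needs at least 3 (x, y) points")
    try:
        return Polygon(flat.reshape(-1, 2))
    except ValueError as exc:
        raise ValidationError(f"annotation {ann_id}: {exc}") from exc


def read_dataset(path: str | Path) -> list[ImageRecord]:
    """Read a COCO-style JSON file into validated :class:`ImageRecord` s.

    ``bbox`` entries are converted from the on-disk ``[x, y, w, h]``
    dialect to internal corner coordinates.  A missing ``px_per_mm``
    falls back to the default 20 px/mm with a logged warning.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: malformed JSON: {exc}") from exc

    records: dict = {}
    for im in doc.get("images", []):
        if "px_per_mm" in im:
            scale = Scale(float(im["px_per_mm"]))
        else:
            logger.warning("image %s: px_per_mm missing, assuming 20 px/mm", im["id"])
            scale = Scale()
        records[im["id"]] = ImageRecord(
            image_id=im["id"],
            width=int(im["width"]),
            height=int(im["height"]),
            scale=scale,
            pg=float(im["pg"]) if im.get("pg") is not None else None,
            year=int(im["year"]) if im.get("year") is not None else None,
        )

    for ann in doc.get("annotations", []):
        ann_id = ann.get("id")
        image_id = ann.get("image_id")
        if image_id not in records:
            raise ValidationError(f"annotation {ann_id}: unknown image_id {image_id}")
        polygon = None
        if ann.get("segmentation"):
            polygon = _segmentation_to_polygon(ann["segmentation"], ann_id)
        box = None
        if ann.get("bbox") is not None:
            x, y, w, h = (float(t) for t in ann["bbox"])
            if w < 0 or h < 0:
                raise ValidationError(f"annotation {ann_id}: negative bbox size")
            box = Box(x, y, x + w, y + h)
        if polygon is not None:
            box = box_from_polygon(polygon)  # invariant: box matches polygon
        try:
            inst = Instance(polygon=polygon, box=box, score=ann.get("score"))
        except ValidationError as exc:
            raise ValidationError(f"annotation {ann_id}: {exc}") from exc
        rec = records[image_id]
        b = inst.box
        if not (0 <= b.xmin and b.xmax <= rec.width and 0 <= b.ymin and b.ymax <= rec.height):
            raise ValidationError(
                f"annotation {ann_id}: coordinates outside image {image_id} bounds"
            )
        rec.instances.append(inst)

    return list(records.values())


def write_dataset(records: Sequence[ImageRecord], path: str | Path) -> None:
    """Write records as COCO-style JSON (bbox serialised as x, y, w, h)."""
    images, annotations = [], []
    ann_id = 1
    for rec in records:
        im: dict = {
            "id": rec.image_id,
            "width": rec.width,
            "height": rec.height,
            "px_per_mm": rec.scale.px_per_mm,
        }
        if rec.pg is not None:
            im["pg"] = rec.pg
        if rec.year is not None:
            im["year"] = rec.year
        images.append(im)
        for inst in rec.instances:
            ann: dict = {
                "id": ann_id,
                "image_id": rec.image_id,
                "category_id": 1,
                "bbox": [inst.box.xmin, inst.box.ymin, inst.box.width, inst.box.height],
            }
            if inst.polygon is not None:
                ann["segmentation"] = [inst.polygon.vertices.ravel().tolist()]
                ann["area"] = inst.polygon.area
            else:
                ann["area"] = inst.box.area
            if inst.score is not None:
                ann["score"] = inst.score
            annotations.append(ann)
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": DEFAULT_CATEGORY}],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def write_report(rows: Iterable[dict], path: str | Path, header_comment: str | None = None) -> None:
    """Write dict rows as CSV with a header row.

    ``header_comment`` (provenance: seed, config hash, version) is written
    as a leading ``#`` line readable by ``pandas.read_csv(comment='#')``.
    """
    rows = list(rows)
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        if not rows:
            return
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)


def split_dataset(
    records: Sequence[ImageRecord],
    train_fraction: float = 0.6,
    seed: int | None = None,
) -> tuple[list[ImageRecord], list[ImageRecord]]:
    """Random image-level train/test split.

    The partition is disjoint at the image level (never by instance, to
    prevent leakage) with ``round(train_fraction * n)`` training images,
    deterministic for a given ``seed``.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_train = int(round(train_fraction * len(records)))
    train = [records[i] for i in sorted(order[:n_train])]
    test = [records[i] for i in sorted(order[n_train:])]
    return train, test
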