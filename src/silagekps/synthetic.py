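"""Synthetic kernel-fragment datasets and a simulated detector.

The field images behind this analysis are not public, so every pipeline
stage is exercised on generated data with the same statistical
structure: per-image sets of convex kernel outlines whose minor-axis
sizes follow a right-skewed (lognormal) law whose location grows with
the processor gap — a wider mill-roll gap leaves larger fragments.

Fragments are polygonised ellipses: convex tangent polygons around a
sampled ellipse, with tangency points at both minor-axis endpoints, so
each fragment's minimal width — its sieve-relevant minor axis — equals
the sampled minor diameter analytically and sizing can be tested as
exact parameter recovery.  The detector model degrades the truth with a miss rate, Poisson
clutter and vertex jitter, and scores detections in proportion to their
localisation quality — a stand-in for a trained network's behaviour at
the statistical level, not a renderer of silage images.

All randomness flows from a single seed through per-sequence spawned
generators, so every dataset is reproducible.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotations import ImageRecord, Instance, SequenceRecord
from .geometry import Polygon, Scale, box_from_polygon, box_iou, convex_hull

__all__ = [
    "SyntheticConfig",
    "DetectorModel",
    "mu_for_below_fraction",
    "generate_dataset",
    "simulate_detector",
    "kps_by_pg_table",
]

# The published per-PG KPS analysis covers 17 sequences over these gaps.
DEFAULT_PG_SEQUENCE = (1.0, 1.0, 1.0, 1.0, 2.0, 2.0, 2.0, 2.0,
                       3.0, 3.0, 3.0, 3.0, 3.5, 3.5, 3.5, 3.5, 3.5)


def default_mu(pg: float) -> float:
    """Lognormal location for the minor-axis law at processor gap ``pg``
    (mm): median minor axis ``1.9 + 0.45 * pg`` mm, increasing in pg."""
    return float(np.log(1.9 + 0.45 * pg))


def mu_for_below_fraction(
    below_fraction: float, sigma: float, threshold_mm: float = 4.75
) -> float:
    """Lognormal ``mu`` such that ``P(size < threshold) = below_fraction``.

    Solves ``Phi((ln t - mu) / sigma) = q`` for ``mu``; used to generate
    datasets whose expected annotation KPS is known analytically.
    """
    if not 0.0 < below_fraction < 1.0:
        raise ValueError("below_fraction must lie in (0, 1)")
    return float(np.log(threshold_mm) - sigma * sps.norm.ppf(below_fraction))


@dataclass(frozen=True)
class SyntheticConfig:
    """Shape and size law of a generated dataset.

    ``pgs`` lists one processor gap per sequence.  Minor axes (mm) are
    lognormal with location ``mu(pg)`` and scale ``sigma``; ``mu_by_pg``
    overrides the default gap-to-location map for specific gaps.
    """

    pgs: tuple[float, ...] = DEFAULT_PG_SEQUENCE
    images_per_sequence: int = 10
    instances_per_image: float = 5.0          # Poisson mean
    sigma: float = 0.35                        # lognormal scale of minor axis, ln-mm
    mu_by_pg: dict | None = None               # pg -> lognormal mu, else default_mu
    # Elongated fragments and fine polygonisation keep the min-area
    # rectangle flush with the ellipse axes, so the measured minor axis
    # recovers the sampled one; near-circular shapes make the min-area
    # rectangle's orientation (and hence its shorter side) unstable.
    aspect_ratio_range: tuple[float, float] = (1.6, 2.6)
    vertex_count_range: tuple[int, int] = (22, 28)
    image_width: int = 1000
    image_height: int = 600
    px_per_mm: float = 20.0
    year: int = 2017
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.pgs, default=1.0) <= 0:
            raise ValueError("processor gaps must be positive")
        if self.images_per_sequence <= 0 or self.instances_per_image <= 0:
            raise ValueError("counts must be positive")
        if self.sigma <= 0 or self.px_per_mm <= 0:
            raise ValueError("sigma and px_per_mm must be positive")
        lo, hi = self.aspect_ratio_range
        if not 1.0 <= lo <= hi:
            raise ValueError("aspect ratios must be >= 1 and ordered")
        vlo, vhi = self.vertex_count_range
        if not 8 <= vlo <= vhi:
            raise ValueError("vertex counts must be >= 8 and ordered")

    def mu(self, pg: float) -> float:
        if self.mu_by_pg is not None and pg in self.mu_by_pg:
            return float(self.mu_by_pg[pg])
        return default_mu(pg)


@dataclass(frozen=True)
class DetectorModel:
    """Statistical stand-in for a trained kernel detector."""

    miss_rate: float = 0.1
    fp_per_image: float = 0.5                  # Poisson mean of clutter per image
    jitter_sd: float = 2.0                     # px, iid Gaussian on each vertex
    score_base: float = 0.95
    score_iou_penalty: float = 0.5             # score drops with (1 - IoU to source)
    score_noise_sd: float = 0.02
    clutter_mu: float = float(np.log(3.0))     # ln-mm minor axis of clutter blobs
    clutter_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.miss_rate <= 1.0:
            raise ValueError("miss_rate must lie in [0, 1]")
        if self.fp_per_image < 0 or self.jitter_sd < 0 or self.score_noise_sd < 0:
            raise ValueError("rates and spreads must be non-negative")


def _ellipse_polygon(
    minor_px: float,
    aspect: float,
    angle_rad: float,
    center: np.ndarray,
    n_vertices: int,
) -> Polygon:
    """Convex polygon circumscribing an ellipse with the given minor
    diameter.  Vertices are intersections of tangent lines at uniformly
    spaced parameters; the phase puts tangency points exactly at both
    minor-axis endpoints (n even), so the polygon lies in the slab of
    width ``minor_px`` across the minor direction and its minimal width
    — hence its measured minor axis — equals ``minor_px`` exactly."""
    n = n_vertices + (n_vertices % 2)          # force even
    b = minor_px / 2.0
    a = b * aspect
    step = 2.0 * np.pi / n
    phase = (np.pi / 2.0) % step
    mids = phase + step * (np.arange(n) + 0.5)
    scale = 1.0 / np.cos(step / 2.0)
    pts = np.stack([a * scale * np.cos(mids), b * scale * np.sin(mids)], axis=1)
    rot = np.array(
        [[np.cos(angle_rad), -np.sin(angle_rad)], [np.sin(angle_rad), np.cos(angle_rad)]]
    )
    return Polygon(pts @ rot.T + center)


def _rotated_ellipse_half_extents(a: float, b: float, angle_rad: float) -> tuple[float, float]:
    ex = np.hypot(a * np.cos(angle_rad), b * np.sin(angle_rad))
    ey = np.hypot(a * np.sin(angle_rad), b * np.cos(angle_rad))
    return float(ex), float(ey)


def _sample_instance(cfg: SyntheticConfig, mu: float, rng: np.random.Generator) -> Instance:
    for _ in range(100):
        minor_mm = float(rng.lognormal(mean=mu, sigma=cfg.sigma))
        aspect = float(rng.uniform(*cfg.aspect_ratio_range))
        angle = float(rng.uniform(0.0, np.pi))
        n_vertices = int(rng.integers(cfg.vertex_count_range[0], cfg.vertex_count_range[1] + 1))
        minor_px = minor_mm * cfg.px_per_mm
        b = minor_px / 2.0
        # circumscribed polygon extends up to 1/cos(pi/n) beyond the ellipse
        pad = 1.0 / np.cos(np.pi / cfg.vertex_count_range[0])
        ex, ey = _rotated_ellipse_half_extents(b * aspect * pad, b * pad, angle)
        if 2 * ex >= cfg.image_width or 2 * ey >= cfg.image_height:
            continue                            # fragment too large; resample
        cx = float(rng.uniform(ex, cfg.image_width - ex))
        cy = float(rng.uniform(ey, cfg.image_height - ey))
        poly = _ellipse_polygon(minor_px, aspect, angle, np.array([cx, cy]), n_vertices)
        return Instance(polygon=poly, meta={"true_minor_mm": minor_mm})
    raise ValueError("could not place an instance inside the image after 100 attempts")


def generate_dataset(cfg: SyntheticConfig) -> list[SequenceRecord]:
    """Generate one annotation sequence per processor gap in ``cfg.pgs``.

    Each image carries Poisson-many convex fragment outlines (at least
    one, so no image is empty) whose true minor axes are recorded in
    ``Instance.meta['true_minor_mm']``.  Deterministic given
    ``cfg.seed``.
    """
    seed_seq = np.random.SeedSequence(cfg.seed)
    children = seed_seq.spawn(len(cfg.pgs))
    sequences = []
    image_id = 1
    for s_idx, (pg, child) in enumerate(zip(cfg.pgs, children), start=1):
        rng = np.random.default_rng(child)
        mu = cfg.mu(pg)
        images = []
        for _ in range(cfg.images_per_sequence):
            n_inst = max(1, int(rng.poisson(cfg.instances_per_image)))
            instances = [_sample_instance(cfg, mu, rng) for _ in range(n_inst)]
            images.append(
                ImageRecord(
                    image_id=image_id,
                    width=cfg.image_width,
                    height=cfg.image_height,
                    scale=Scale(cfg.px_per_mm),
                    pg=pg,
                    year=cfg.year,
                    instances=instances,
                )
            )
            image_id += 1
        sequences.append(SequenceRecord(sequence_id=s_idx, pg=pg, images=images))
    return sequences


def _clamp_polygon(poly: Polygon, width: int, height: int) -> Polygon:
    v = poly.vertices.copy()
    v[:, 0] = np.clip(v[:, 0], 0.0, width)
    v[:, 1] = np.clip(v[:, 1], 0.0, height)
    return convex_hull(Polygon(v))


def _score(det_model: DetectorModel, iou: float, rng: np.random.Generator) -> float:
    s = det_model.score_base - det_model.score_iou_penalty * (1.0 - iou)
    s += float(rng.normal(0.0, det_model.score_noise_sd)) if det_model.score_noise_sd else 0.0
    return float(np.clip(s, 0.0, 1.0))


def simulate_detector(
    truth: list[SequenceRecord], det: DetectorModel
) -> list[SequenceRecord]:
    """Degrade ground truth into scored detections.

    Each true fragment is missed with probability ``miss_rate``;
    survivors get iid Gaussian vertex jitter (re-convexified, clipped to
    the image).  Poisson-many clutter fragments are added per image.
    Scores fall with localisation quality: ``base - penalty * (1 - IoU)``
    plus noise, where IoU is the box IoU to the source fragment (0 for
    clutter).  Deterministic given ``det.seed``.
    """
    seed_seq = np.random.SeedSequence(det.seed)
    children = seed_seq.spawn(len(truth))
    out = []
    for seq, child in zip(truth, children):
        rng = np.random.default_rng(child)
        det_images = []
        for im in seq.images:
            dets: list[Instance] = []
            for inst in im.instances:
                if rng.uniform() < det.miss_rate:
                    continue
                poly = inst.polygon
                if det.jitter_sd > 0:
                    v = poly.vertices + rng.normal(0.0, det.jitter_sd, poly.vertices.shape)
                    poly = _clamp_polygon(Polygon(v), im.width, im.height)
                else:
                    poly = _clamp_polygon(poly, im.width, im.height)
                iou = box_iou(box_from_polygon(poly), inst.box)
                dets.append(
                    Instance(polygon=poly, score=_score(det, iou, rng),
                             meta={"source": "gt"})
                )
            n_fp = int(rng.poisson(det.fp_per_image))
            for _ in range(n_fp):
                minor_mm = float(rng.lognormal(det.clutter_mu, det.clutter_sigma))
                aspect = float(rng.uniform(1.6, 2.6))
                angle = float(rng.uniform(0.0, np.pi))
                minor_px = minor_mm * im.scale.px_per_mm
                b = minor_px / 2.0
                ex, ey = _rotated_ellipse_half_extents(b * aspect, b, angle)
                if 2 * ex >= im.width or 2 * ey >= im.height:
                    continue
                cx = float(rng.uniform(ex, im.width - ex))
                cy = float(rng.uniform(ey, im.height - ey))
                poly = _ellipse_polygon(minor_px, aspect, angle, np.array([cx, cy]), 12)
                dets.append(
                    Instance(polygon=poly, score=_score(det, 0.0, rng),
                             meta={"source": "clutter"})
                )
            det_images.append(
                ImageRecord(
                    image_id=im.image_id, width=im.width, height=im.height,
                    scale=im.scale, pg=im.pg, year=im.year, instances=dets,
                )
            )
        out.append(SequenceRecord(sequence_id=seq.sequence_id, pg=seq.pg, images=det_images))
    return out


def kps_by_pg_table() -> pd.DataFrame:
    """The embedded published per-PG KPS table: 17 sequences, eight
    model columns (bounding-box and segmentation networks trained per
    harvest year and on the combined set) plus the annotation column."""
    ref = importlib.resources.files("silagekps.data").joinpath("kps_by_pg.csv")
    with ref.open() as fh:
        return pd.read_csv(fh)
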