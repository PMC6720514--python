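"""Pixel-space computational geometry for kernel-fragment sizing.

Everything here works in image coordinates: the origin at the top-left
corner, ``x`` increasing rightward and ``y`` increasing downward, one unit
per pixel.  Fragments are outlined as polygons; their size is taken from
the minimum-area rotated rectangle enclosing the outline, whose shorter
side (the minor axis) is the length that governs whether a fragment would
pass a sieve screen.

The rectangle is found by the rotating-calipers argument: the minimum-area
enclosing rectangle of a convex polygon has one side flush with a hull
edge, so it suffices to test one orientation per edge of the convex hull.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

__all__ = [
    "DegenerateGeometryError",
    "UndefinedIoUError",
    "Polygon",
    "Box",
    "RotatedRect",
    "Scale",
    "convex_hull",
    "min_area_rect",
    "box_from_polygon",
    "box_iou",
    "mask_iou",
    "px_to_mm",
]


class DegenerateGeometryError(ValueError):
    """Raised when a polygon has no interior (fewer than 3 distinct
    non-collinear vertices, or zero hull area)."""


class UndefinedIoUError(ValueError):
    """Raised when intersection-over-union is requested for two empty
    regions, where the ratio 0/0 has no meaning."""


@dataclass(frozen=True)
class Polygon:
    """Closed polygon outlining one kernel fragment.

    Parameters
    ----------
    vertices
        Ordered ``(n, 2)`` array-like of ``(x, y)`` pixel coordinates.
        The outline is implicitly closed (the last vertex connects back
        to the first).  Consecutive duplicate vertices are dropped on
        construction.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError(f"vertices must be an (n, 2) array, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("polygon vertices must be finite")
        # drop consecutive duplicates (incl. a duplicated closing vertex)
        keep = np.any(v != np.roll(v, 1, axis=0), axis=1)
        if keep.any():
            v = v[keep]
        if len(v) < 3:
            raise ValueError("polygon needs at least 3 distinct vertices")
        object.__setattr__(self, "vertices", v)
        if self.area == 0.0:
            raise ValueError("polygon has zero area")

    @property
    def area(self) -> float:
        """Unsigned shoelace area in square pixels."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))) / 2.0

    def translated(self, dx: float, dy: float) -> "Polygon":
        return Polygon(self.vertices + np.array([dx, dy]))

    def rotated(self, angle_deg: float, center: tuple[float, float] = (0.0, 0.0)) -> "Polygon":
        """Rigidly rotate the outline by ``angle_deg`` about ``center``."""
        a = np.deg2rad(angle_deg)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        c = np.asarray(center, dtype=float)
        return Polygon((self.vertices - c) @ rot.T + c)

    def to_shapely(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)


@dataclass(frozen=True)
class Box:
    """Axis-aligned box in pixel corner coordinates."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax >= self.xmin and self.ymax >= self.ymin):
            raise ValueError(
                f"invalid box ({self.xmin}, {self.ymin}, {self.xmax}, {self.ymax})"
            )

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def shortest_side(self) -> float:
        return min(self.width, self.height)

    def to_polygon(self) -> Polygon:
        return Polygon(
            [
                (self.xmin, self.ymin),
                (self.xmax, self.ymin),
                (self.xmax, self.ymax),
                (self.xmin, self.ymax),
            ]
        )


@dataclass(frozen=True)
class RotatedRect:
    """Minimum-area enclosing rectangle.

    ``side_a >= side_b``; ``side_b`` is the minor axis used for sieve-size
    scoring.  ``angle`` is the direction of ``side_a`` from the +x axis in
    degrees, normalised to ``[0, 180)`` to remove the four-fold symmetry
    of rectangle parameterisations.
    """

    center: tuple[float, float]
    side_a: float
    side_b: float
    angle: float

    def __post_init__(self) -> None:
        if not (self.side_a >= self.side_b >= 0.0):
            raise ValueError("requires side_a >= side_b >= 0")
        if not (0.0 <= self.angle < 180.0):
            raise ValueError("angle must lie in [0, 180)")

    @property
    def minor_axis(self) -> float:
        return self.side_b

    @property
    def area(self) -> float:
        return self.side_a * self.side_b

    def corners(self) -> np.ndarray:
        """The four rectangle corners, ``(4, 2)``."""
        a = np.deg2rad(self.angle)
        u = np.array([np.cos(a), np.sin(a)])
        v = np.array([-np.sin(a), np.cos(a)])
        c = np.asarray(self.center)
        ha, hb = self.side_a / 2.0, self.side_b / 2.0
        return np.array(
            [c - ha * u - hb * v, c + ha * u - hb * v, c + ha * u + hb * v, c - ha * u + hb * v]
        )


@dataclass(frozen=True)
class Scale:
    """Image resolution as pixels per millimetre (default 20 px/mm,
    i.e. 0.05 mm per pixel)."""

    px_per_mm: float = 20.0

    def __post_init__(self) -> None:
        if not self.px_per_mm > 0:
            raise ValueError("px_per_mm must be strictly positive")


def _cross(o: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull(p: Polygon) -> Polygon:
    """Convex hull of the polygon vertices (Andrew's monotone chain).

    Returns the hull as a new :class:`Polygon` with vertices in
    counter-clockwise order (in the coordinate algebra sense); collinear
    points are dropped.

    Raises
    ------
    DegenerateGeometryError
        If fewer than 3 distinct non-collinear vertices remain.
    """
    pts = np.unique(p.vertices, axis=0)
    if len(pts) < 3:
        raise DegenerateGeometryError("fewer than 3 distinct vertices")
    # lexicographic sort by (x, y)
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]

    def half(points: np.ndarray) -> list[np.ndarray]:
        chain: list[np.ndarray] = []
        for q in points:
            while len(chain) >= 2 and _cross(chain[-2], chain[-1], q) <= 0:
                chain.pop()
            chain.append(q)
        return chain

    lower = half(pts)
    upper = half(pts[::-1])
    hull = np.array(lower[:-1] + upper[:-1])
    if len(hull) < 3:
        raise DegenerateGeometryError("vertices are collinear")
    return Polygon(hull)


def min_area_rect(p: Polygon) -> RotatedRect:
    """Minimum-area rotated rectangle enclosing the polygon.

    One rectangle side is flush with a convex-hull edge (rotating
    calipers); among all hull-edge orientations the smallest extent
    product wins.  ``side_b`` of the result is the fragment's minor axis.
    """
    hull = convex_hull(p).vertices
    edges = np.roll(hull, -1, axis=0) - hull
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    u = edges / lengths[:, None]            # unit edge directions, (m, 2)
    v = np.stack([-u[:, 1], u[:, 0]], axis=1)

    pu = u @ hull.T                          # (m, n) projections
    pv = v @ hull.T
    ext_u = pu.max(axis=1) - pu.min(axis=1)
    ext_v = pv.max(axis=1) - pv.min(axis=1)
    areas = ext_u * ext_v
    i = int(np.argmin(areas))

    cu = (pu[i].max() + pu[i].min()) / 2.0
    cv = (pv[i].max() + pv[i].min()) / 2.0
    center = cu * u[i] + cv * v[i]

    theta = np.degrees(np.arctan2(u[i, 1], u[i, 0]))
    if ext_u[i] >= ext_v[i]:
        side_a, side_b = float(ext_u[i]), float(ext_v[i])
    else:
        side_a, side_b = float(ext_v[i]), float(ext_u[i])
        theta += 90.0
    theta %= 180.0
    if theta == 180.0:  # guard against -0.0 % wraparound
        theta = 0.0
    return RotatedRect(center=(float(center[0]), float(center[1])),
                       side_a=side_a, side_b=side_b, angle=theta)


def box_from_polygon(p: Polygon) -> Box:
    """Axis-aligned box from the coordinate extremes of the vertices."""
    x, y = p.vertices[:, 0], p.vertices[:, 1]
    return Box(float(x.min()), float(y.min()), float(x.max()), float(y.max()))


def box_iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two axis-aligned boxes.

    Raises
    ------
    UndefinedIoUError
        If both boxes have zero area.
    """
    if a.area == 0.0 and b.area == 0.0:
        raise UndefinedIoUError("IoU of two zero-area boxes is undefined")
    iw = min(a.xmax, b.xmax) - max(a.xmin, b.xmin)
    ih = min(a.ymax, b.ymax) - max(a.ymin, b.ymin)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    inter = iw * ih
    union = a.area + b.area - inter
    return inter / union


def _raster_mask(geom: shapely.Polygon, x0: int, y0: int, nx: int, ny: int) -> np.ndarray:
    """Pixel-centre containment mask over the grid of pixels
    ``[x0, x0+nx) x [y0, y0+ny)`` (pixel (i, j) has centre (i+.5, j+.5))."""
    xs = x0 + np.arange(nx) + 0.5
    ys = y0 + np.arange(ny) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    return shapely.contains_xy(geom, gx.ravel(), gy.ravel()).reshape(ny, nx)


def mask_iou(a: Polygon, b: Polygon) -> float:
    """IoU of the rasterised polygon interiors.

    Both polygons are rasterised on the native integer pixel grid with
    pixel-centre containment (standard instance-segmentation practice);
    the IoU is the ratio of shared to combined pixel counts.

    Raises
    ------
    UndefinedIoUError
        If both polygons rasterise to the empty pixel set.
    """
    ga, gb = a.to_shapely(), b.to_shapely()
    allv = np.vstack([a.vertices, b.vertices])
    x0 = int(np.floor(allv[:, 0].min()))
    y0 = int(np.floor(allv[:, 1].min()))
    nx = max(int(np.ceil(allv[:, 0].max())) - x0, 1)
    ny = max(int(np.ceil(allv[:, 1].max())) - y0, 1)
    ma = _raster_mask(ga, x0, y0, nx, ny)
    mb = _raster_mask(gb, x0, y0, nx, ny)
    union = int(np.logical_or(ma, mb).sum())
    if union == 0:
        raise UndefinedIoUError("both polygons rasterise to the empty set")
    inter = int(np.logical_and(ma, mb).sum())
    return inter / union


def px_to_mm(length_px: float, s: Scale | None = None) -> float:
    """Convert a pixel length to millimetres (``length_px / px_per_mm``)."""
    if length_px < 0:
        raise ValueError("length must be non-negative")
    if s is None:
        s = Scale()
    return length_px / s.px_per_mm
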