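import numpy as np
import pytest

from silagekps import Polygon, convex_hull
from silagekps.synthetic import kps_by_pg_table

MODEL_COLUMNS = (
    "rfcn_2015", "mnc_2015", "rfcn_2016", "mnc_2016",
    "rfcn_2017", "mnc_2017", "rfcn_151617", "mnc_151617",
)


@pytest.fixture(scope="session")
def kps_table_published():
    """The embedded 17-sequence per-PG KPS table."""
    return kps_by_pg_table()


def random_convex_polygon(rng: np.random.Generator, n_points: int = 12) -> Polygon:
    """Random convex polygon: convex hull of a random point cloud."""
    while True:
        pts = rng.uniform(0, 100, size=(max(n_points, 8), 2))
        try:
            return convex_hull(Polygon(pts))
        except ValueError:
            continue


def _sweep_areas(vertices: np.ndarray, ang: np.ndarray) -> np.ndarray:
    u = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    v = np.stack([-np.sin(ang), np.cos(ang)], axis=1)
    pu = u @ vertices.T
    pv = v @ vertices.T
    return (pu.max(1) - pu.min(1)) * (pv.max(1) - pv.min(1))


def sweep_min_rect_area(vertices: np.ndarray, step_deg: float = 0.01) -> float:
    """Brute-force oracle: minimum enclosing-rectangle area over an
    exhaustive angle sweep (projection extents at each orientation),
    refined around the best coarse angle so the discretisation error is
    far below the comparison tolerance."""
    ang = np.deg2rad(np.arange(0.0, 90.0, step_deg))
    areas = _sweep_areas(vertices, ang)
    best = float(ang[int(np.argmin(areas))])
    lo = float(areas.min())
    half = np.deg2rad(step_deg)
    for _ in range(3):  # each pass shrinks the window 100-fold
        fine = np.linspace(best - half, best + half, 201)
        fareas = _sweep_areas(vertices, fine)
        best = float(fine[int(np.argmin(fareas))])
        lo = min(lo, float(fareas.min()))
        half /= 100.0
    return lo
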