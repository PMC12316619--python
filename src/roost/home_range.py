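"""Seasonal home ranges: concentric MCPs, 95% MCP, and href-kernel UD.

Two estimators of the seasonal range boundary, matching standard
practice in collar studies:

* **MCP** — points are ranked by distance to their geographic mean; the
  convex hull over the most central fraction (default 95%) is the range.
  The concentric profile (hull area at 5%, 10%, ..., 100%) exposes the
  outlier knee that motivates trimming the least-central 5%.
* **KDE** — a bivariate Gaussian kernel utilization distribution with
  the reference ("href") bandwidth h = sigma * n^(-1/6), where sigma is
  the mean of the coordinate standard deviations; the range is the
  smallest-density contour enclosing the target fraction of the
  estimated mass (the 95% isopleth).

Distances from a sleep anchor to the range edge are unsigned: a point
outside the boundary is as far from the edge as a point the same
distance inside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import unary_union
from scipy.ndimage import gaussian_filter
from skimage import measure


@dataclass
class HomeRange:
    troop_id: str
    season: str
    method: str  # "MCP" | "KDE"
    level: float
    polygons: list[Polygon]

    @property
    def area_m2(self) -> float:
        return float(sum(p.area for p in self.polygons))


@dataclass(frozen=True)
class CentralityProfile:
    fractions: np.ndarray
    areas_m2: np.ndarray


def _central_order(points: np.ndarray) -> np.ndarray:
    """Indices sorted by distance to the geographic mean (ties by index)."""
    center = points.mean(axis=0)
    d = np.hypot(points[:, 0] - center[0], points[:, 1] - center[1])
    return np.argsort(d, kind="stable")


def _hull(points: np.ndarray) -> Polygon:
    hull = MultiPoint([tuple(p) for p in points]).convex_hull
    if isinstance(hull, Polygon):
        return hull
    return hull.buffer(0.0) if hull.area > 0 else Polygon()


def concentric_mcp_profile(points: np.ndarray) -> CentralityProfile:
    """Hull areas over the central 5%, 10%, ..., 100% of points.

    Degenerate (collinear) subsets have zero area.  Areas are
    non-decreasing because each subset nests in the next.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 20:
        raise ValueError("need >= 20 points for a centrality profile")
    order = _central_order(pts)
    fracs = np.arange(0.05, 1.0001, 0.05)
    areas = np.empty(len(fracs))
    for i, f in enumerate(fracs):
        k = max(1, int(np.ceil(f * len(pts) - 1e-9)))
        areas[i] = _hull(pts[order[:k]]).area
    return CentralityProfile(fractions=fracs, areas_m2=areas)


def mcp_home_range(
    points: np.ndarray,
    level: float = 0.95,
    troop_id: str = "",
    season: str = "",
) -> HomeRange:
    """Convex hull over the ``level`` most-central points."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 20:
        raise ValueError("need >= 20 points for an MCP home range")
    if not 0.0 < level <= 1.0:
        raise ValueError("level must be in (0, 1]")
    order = _central_order(pts)
    k = max(3, int(np.ceil(level * len(pts) - 1e-9)))
    hull = _hull(pts[order[:k]])
    return HomeRange(
        troop_id=troop_id, season=season, method="MCP", level=level,
        polygons=[hull],
    )


def href_bandwidth(points: np.ndarray) -> float:
    """Reference bandwidth h = sigma * n^(-1/6), sigma = (sd_x + sd_y)/2."""
    pts = np.asarray(points, dtype=float)
    sd = 0.5 * (pts[:, 0].std(ddof=1) + pts[:, 1].std(ddof=1))
    if sd == 0:
        raise ValueError("zero-variance input: bandwidth undefined")
    return float(sd * len(pts) ** (-1.0 / 6.0))


def kde_home_range(
    points: np.ndarray,
    level: float = 0.95,
    grid_res_m: float = 50.0,
    troop_id: str = "",
    season: str = "",
) -> HomeRange:
    """Isopleth of a Gaussian-kernel utilization distribution.

    The UD is estimated by binning fixes on a regular grid (resolution
    capped at h/3 so the kernel is well resolved) padded 3h beyond the
    data extent, then convolving with an isotropic Gaussian of the href
    bandwidth.  The boundary is the density contour whose superlevel set
    holds >= ``level`` of the grid-integrated mass; disjoint modes yield
    multiple polygons.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 30:
        raise ValueError("need >= 30 points for a KDE home range")
    h = href_bandwidth(pts)
    res = min(grid_res_m, h / 3.0)
    pad = 3.0 * h + res
    x0, y0 = pts.min(axis=0) - pad
    x1, y1 = pts.max(axis=0) + pad
    nx = int(np.ceil((x1 - x0) / res)) + 1
    ny = int(np.ceil((y1 - y0) / res)) + 1

    ix = np.clip(((pts[:, 0] - x0) / res).round().astype(int), 0, nx - 1)
    iy = np.clip(((pts[:, 1] - y0) / res).round().astype(int), 0, ny - 1)
    grid = np.zeros((ny, nx))
    np.add.at(grid, (iy, ix), 1.0)
    dens = gaussian_filter(grid, sigma=h / res, mode="constant", truncate=5.0)
    dens /= dens.sum() * res * res  # integrates to 1 over the grid

    # smallest-density superlevel set holding >= level of the mass
    flat = np.sort(dens.ravel())[::-1]
    csum = np.cumsum(flat) * res * res
    k = int(np.searchsorted(csum, level))
    lam = flat[min(k, len(flat) - 1)]

    padded = np.pad(dens, 1, constant_values=0.0)  # closes boundary contours
    contours = measure.find_contours(padded, lam)
    polys = []
    for c in contours:
        # rows are y, cols are x; remove the pad offset, scale to metres
        xs = x0 + (c[:, 1] - 1) * res
        ys = y0 + (c[:, 0] - 1) * res
        if len(xs) >= 4:
            poly = Polygon(zip(xs, ys))
            if poly.is_valid and poly.area > 0:
                polys.append(poly)
    # keep outer shells only: drop any ring nested inside another
    shells = [
        p for p in polys
        if not any(q is not p and q.contains(p) for q in polys)
    ]
    merged = unary_union(shells)
    if isinstance(merged, Polygon):
        shells = [merged]
    else:
        shells = [g for g in merged.geoms if isinstance(g, Polygon)]
    return HomeRange(
        troop_id=troop_id, season=season, method="KDE", level=level,
        polygons=shells,
    )


def distance_to_edge(point: tuple[float, float], hr: HomeRange) -> float:
    """Unsigned straight-line metres from a point to the nearest boundary
    segment of any range polygon, inside or out."""
    if not hr.polygons:
        raise ValueError("home range has no polygons")
    p = Point(point)
    return float(min(p.distance(poly.exterior) for poly in hr.polygons))
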