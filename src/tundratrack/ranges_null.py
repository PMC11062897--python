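"""Home ranges, availability domains, and the translate-rotate null model.

Seasonal home ranges are 100% adaptive local convex hulls (a-LoCoH):
each fix roots a local hull over the neighbors whose cumulative distance to
the root stays within the budget ``a`` (default: maximum pairwise distance),
and the 100% isopleth is the union of local hulls, preserving holes and
concavities such as lakes. Availability is the pooled-season 100% minimum
convex polygon, dilated by the radius of the circle whose area is the mean
individual MCP, minus non-habitat (water). Availability of habitat is then
operationalized by rigidly translating and rotating each observed home
range across the availability domain (used:available 1:5 in summer, 1:10
in winter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from shapely import affinity
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import unary_union
from shapely.prepared import prep

from .raster import Raster

__all__ = [
    "HomeRange",
    "AvailabilityDomain",
    "mcp",
    "alocoh",
    "range_stability",
    "water_polygons",
    "availability_area",
    "random_home_ranges",
]


@dataclass
class HomeRange:
    individual_id: str
    season: str
    polygon: shapely.Geometry  # Polygon or MultiPolygon, holes allowed
    n_fixes: int

    def __post_init__(self) -> None:
        if not self.polygon.is_valid:
            self.polygon = shapely.make_valid(self.polygon)
        if self.polygon.area <= 0:
            raise ValueError("home range must have positive area")

    @property
    def area_km2(self) -> float:
        return self.polygon.area / 1e6


@dataclass
class AvailabilityDomain:
    season: str
    polygon: shapely.Geometry
    buffer_radius_m: float

    @property
    def area_km2(self) -> float:
        return self.polygon.area / 1e6


def _points_array(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of x, y")
    return pts


def mcp(points, percent: float = 100.0) -> Polygon:
    """100% minimum convex polygon (convex hull) of points."""
    pts = _points_array(points)
    if percent != 100.0:
        raise NotImplementedError("only the 100% MCP is supported")
    if len(pts) < 3:
        raise ValueError("MCP needs at least 3 points")
    hull = MultiPoint(pts).convex_hull
    if hull.area <= 0:
        raise ValueError("points are collinear; MCP undefined")
    return hull


def alocoh(points, a: float | None = None, individual_id: str = "?",
           season: str = "?") -> HomeRange:
    """100% a-LoCoH home range.

    For every root point, neighbors are added in order of increasing
    distance while the cumulative distance sum stays <= ``a`` (at least the
    two nearest neighbors are always included so each root spans a hull);
    the 100% isopleth is the union of all local hulls.
    """
    pts = _points_array(points)
    if len(pts) < 3:
        raise ValueError("a-LoCoH needs at least 3 points")
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    if a is None:
        a = float(d.max())
    hulls = []
    for i in range(len(pts)):
        order = np.argsort(d[i], kind="stable")
        cum = np.cumsum(d[i][order])
        k = int(np.searchsorted(cum, a, side="right"))
        k = max(k, 3)  # root + >= 2 neighbors
        hulls.append(MultiPoint(pts[order[:k]]).convex_hull)
    iso = unary_union(hulls)
    if iso.area <= 0:
        raise ValueError("degenerate (collinear) point set")
    return HomeRange(individual_id=individual_id, season=season,
                     polygon=iso, n_fixes=len(pts))


def range_stability(points, step: int = 5, min_n: int = 50,
                    final_fraction: float = 0.2, tol: float = 0.15,
                    max_curve_points: int = 15):
    """Area-observation curve and stability flag.

    The a-LoCoH area is computed on increasing chronological prefixes,
    holding the distance budget ``a`` fixed at its full-dataset value so
    the curve reflects data quantity rather than the growth of the
    heuristic itself. An individual is stable when n > ``min_n`` AND the
    area varies by less than ``tol`` (relative to the final area) over the
    last ``final_fraction`` of the curve; unstable individuals are
    excluded from habitat-selection fits.
    """
    pts = _points_array(points)
    n = len(pts)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    a_full = float(d.max())
    sizes = np.arange(step, n + 1, step)
    if len(sizes) == 0 or sizes[-1] != n:
        sizes = np.append(sizes, n)
    if len(sizes) > max_curve_points:  # thin the curve, keep endpoints
        keep = np.unique(np.linspace(0, len(sizes) - 1,
                                     max_curve_points).round().astype(int))
        sizes = sizes[keep]
    areas = []
    for k in sizes:
        try:
            areas.append(alocoh(pts[:k], a=a_full).area_km2)
        except ValueError:
            areas.append(np.nan)
    areas = np.asarray(areas)
    stable = False
    if n > min_n and np.isfinite(areas[-1]) and areas[-1] > 0:
        tail = areas[sizes >= (1 - final_fraction) * n]
        tail = tail[np.isfinite(tail)]
        if len(tail) >= 2:
            stable = (tail.max() - tail.min()) / areas[-1] < tol
    return {"n": sizes, "area_km2": areas}, bool(stable)


def water_polygons(water_mask: Raster) -> shapely.Geometry:
    """Union of water cells as polygons (row runs merged into rectangles)."""
    vals = water_mask.values > 0
    cs = water_mask.cell_size
    boxes = []
    for i in range(water_mask.n_rows):
        row = vals[i]
        j = 0
        y1 = water_mask.origin_y - i * cs
        while j < len(row):
            if row[j]:
                j0 = j
                while j + 1 < len(row) and row[j + 1]:
                    j += 1
                boxes.append(shapely.box(
                    water_mask.origin_x + j0 * cs, y1 - cs,
                    water_mask.origin_x + (j + 1) * cs, y1))
            j += 1
    return unary_union(boxes) if boxes else Polygon()


def availability_area(points_by_individual: dict, season: str,
                      water_mask: Raster | None = None,
                      buffer_radius_m: float | None = None,
                      extent=None) -> AvailabilityDomain:
    """Seasonal availability domain.

    The pooled 100% MCP over all individuals' fixes, dilated by the radius
    of the circle of area equal to the mean individual 100% MCP (or a
    forced ``buffer_radius_m``), minus water, clipped to ``extent``
    ((xmin, ymin, xmax, ymax), e.g. the mapped area) when given. The
    radius actually applied is reported on the domain.
    """
    all_pts = np.vstack([_points_array(p) for p in
                         points_by_individual.values()])
    pooled = mcp(all_pts)
    if buffer_radius_m is None:
        areas = []
        for pts in points_by_individual.values():
            try:
                areas.append(mcp(pts).area)
            except ValueError:
                continue
        if not areas:
            raise ValueError("no individual MCP could be computed")
        buffer_radius_m = float(np.sqrt(np.mean(areas) / np.pi))
    domain = pooled.buffer(buffer_radius_m)
    if extent is not None:
        domain = domain.intersection(shapely.box(*extent))
    if water_mask is not None:
        water = water_polygons(water_mask)
        if not water.is_empty:
            domain = domain.difference(water)
    return AvailabilityDomain(season=season, polygon=domain,
                              buffer_radius_m=float(buffer_radius_m))


def random_home_ranges(hr: HomeRange, domain: AvailabilityDomain,
                       ratio: int, seed=None, max_tries: int = 10_000,
                       rng: np.random.Generator | None = None):
    """Rigid random copies of a home range inside the availability domain.

    Each copy is rotated uniformly on [0, 2pi) about its centroid and
    translated so the centroid lands uniformly in the domain's bounding
    box; a pose is accepted only when the whole polygon lies inside the
    domain. Areas are preserved exactly (rigid motion). Raises when
    ``max_tries`` poses fail for any single copy.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = domain.polygon.bounds
    out, rejections = [], 0
    domain_prep = prep(domain.polygon)
    for _ in range(int(ratio)):
        for attempt in range(max_tries):
            ang = rng.uniform(0.0, 360.0)
            tx = rng.uniform(xmin, xmax)
            ty = rng.uniform(ymin, ymax)
            poly = affinity.rotate(hr.polygon, ang, origin="centroid")
            c = poly.centroid
            poly = affinity.translate(poly, xoff=tx - c.x, yoff=ty - c.y)
            if domain_prep.contains(poly):
                out.append(poly)
                break
            rejections += 1
        else:
            raise RuntimeError(
                f"could not place home range {hr.individual_id!r} in the "
                f"{domain.season} availability domain after {max_tries} "
                "tries (domain too small)")
    return out, rejections
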