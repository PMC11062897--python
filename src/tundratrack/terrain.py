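"""Environmental variables derived from raw rasters.

Covers the covariate stack used throughout: soil-adjusted vegetation index
(SAVI), elevation, Horn slope and aspect, aspect classes and their
trigonometric transforms (northness/eastness), and the arc-chord-ratio
(ACR) rugosity index. Conventions: slope in degrees; aspect is the
downslope direction in degrees clockwise from north, on [0, 360), nodata
where the surface is flat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve
from shapely.geometry import Polygon

from .raster import Raster

__all__ = [
    "TerrainStack",
    "compute_savi",
    "slope_aspect",
    "aspect_features",
    "acr_rugosity",
    "resample",
    "build_terrain_stack",
]

#: Aspect class intervals, degrees clockwise from north, half-open with
#: North owning [315, 45).
ASPECT_CLASSES = ("N", "E", "S", "W")


def compute_savi(nir: Raster, red: Raster, L: float = 0.5,
                 water_mask: Raster | None = None) -> Raster:
    """Soil-adjusted vegetation index, (NIR - Red)(1 + L)/(NIR + Red + L).

    The soil-adjustment constant L (default 0.5) damps soil-brightness
    effects in sparse cover; L = 0 recovers NDVI. Nodata propagates;
    water-masked cells become nodata.
    """
    if not nir.same_grid(red):
        raise ValueError("NIR and Red rasters must share grid geometry")
    denom = nir.values + red.values + L
    with np.errstate(invalid="ignore", divide="ignore"):
        savi = (nir.values - red.values) * (1.0 + L) / denom
    savi = np.where(denom == 0, np.nan, savi)
    if water_mask is not None:
        if not nir.same_grid(water_mask):
            raise ValueError("water mask must share grid geometry")
        savi = np.where(water_mask.values > 0, np.nan, savi)
    return nir.copy_with(savi)


def slope_aspect(dem: Raster) -> tuple[Raster, Raster]:
    """Slope (degrees) and aspect (degrees clockwise from north) by Horn's
    3x3 finite differences.

    Aspect is the downslope direction; flat cells (zero gradient) get
    nodata aspect. Edges use replicated padding.
    """
    if dem.n_rows < 3 or dem.n_cols < 3:
        raise ValueError("DEM must be at least 3x3 cells")
    z = dem.values
    cs = dem.cell_size
    # Horn kernels; row 0 is the northern row, so +row is southward.
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]) / (8.0 * cs)
    ky = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]]) / (8.0 * cs)
    gx = convolve(z, kx[::-1, ::-1], mode="nearest")  # dz/dx (east)
    gy = convolve(z, ky[::-1, ::-1], mode="nearest")  # dz/dy (north)
    grad = np.hypot(gx, gy)
    slope = np.degrees(np.arctan(grad))
    # downslope vector is -grad; compass bearing from (east, north) comps
    aspect = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    aspect = np.where(grad == 0, np.nan, aspect)
    bad = np.isnan(z)
    return (dem.copy_with(np.where(bad, np.nan, slope)),
            dem.copy_with(np.where(bad, np.nan, aspect)))


def aspect_features(aspect: Raster) -> tuple[Raster, Raster, Raster]:
    """Aspect class (0=N, 1=E, 2=S, 3=W), northness = cos(aspect) and
    eastness = sin(aspect). Flat (nodata-aspect) cells are nodata in all
    three outputs."""
    a = aspect.values
    rad = np.radians(a)
    northness = np.cos(rad)
    eastness = np.sin(rad)
    cls = np.full(a.shape, np.nan)
    ok = np.isfinite(a)
    av = np.mod(a[ok], 360.0)
    c = np.full(av.shape, 0.0)           # North: [315, 360) u [0, 45)
    c[(av >= 45) & (av < 135)] = 1.0     # East
    c[(av >= 135) & (av < 225)] = 2.0    # South
    c[(av >= 225) & (av < 315)] = 3.0    # West
    cls[ok] = c
    return (aspect.copy_with(cls, categorical=True),
            aspect.copy_with(northness),
            aspect.copy_with(eastness))


def acr_rugosity(dem: Raster, region: Polygon) -> float:
    """Arc-chord ratio rugosity over a region.

    Ratio of the 3-D triangulated surface area of the DEM over the region
    to the area of that surface projected onto the least-squares plane
    fitted to the region's boundary cells. By construction the index is
    >= 1 and equals 1 on any plane (flat or tilted), decoupling rugosity
    from slope.
    """
    import shapely

    X, Y = dem.center_grids()
    inside = shapely.contains_xy(region, X.ravel(), Y.ravel()).reshape(X.shape)
    inside &= np.isfinite(dem.values)
    if inside.sum() < 4:
        raise ValueError("region must cover at least a 2x2 block of cells")

    # boundary cells: inside cells with a 4-neighbor outside the region
    pad = np.pad(inside, 1, constant_values=False)
    nbrs = (pad[:-2, 1:-1].astype(int) + pad[2:, 1:-1] + pad[1:-1, :-2]
            + pad[1:-1, 2:])
    boundary = inside & (nbrs < 4)
    bx, by = X[boundary], Y[boundary]
    bz = dem.values[boundary]
    A = np.column_stack([bx, by, np.ones_like(bx)])
    if np.linalg.matrix_rank(A) < 3:
        raise ValueError("degenerate (collinear) region boundary")
    coef, *_ = np.linalg.lstsq(A, bz, rcond=None)
    n_plane = np.array([-coef[0], -coef[1], 1.0])
    n_plane /= np.linalg.norm(n_plane)

    # triangulate 2x2 blocks of in-region cell centers
    q = inside[:-1, :-1] & inside[:-1, 1:] & inside[1:, :-1] & inside[1:, 1:]
    qi, qj = np.nonzero(q)
    if len(qi) == 0:
        raise ValueError("region must cover at least a 2x2 block of cells")

    def corner(di, dj):
        i, j = qi + di, qj + dj
        return np.column_stack([X[i, j], Y[i, j], dem.values[i, j]])

    p00, p01, p10, p11 = corner(0, 0), corner(0, 1), corner(1, 0), corner(1, 1)
    area3d = 0.0
    chord = 0.0
    for a, b, c in ((p00, p01, p11), (p00, p11, p10)):
        n = np.cross(b - a, c - a)
        tri = 0.5 * np.linalg.norm(n, axis=1)
        area3d += tri.sum()
        with np.errstate(invalid="ignore"):
            cosang = np.abs(n @ n_plane) / np.linalg.norm(n, axis=1)
        chord += np.nansum(tri * cosang)
    return float(area3d / chord)


def resample(raster: Raster, target_cell: float = 10.0,
             method: str = "bilinear") -> Raster:
    """Resample onto a grid with ``target_cell`` spacing and the same
    north-west origin. Continuous layers use bilinear interpolation;
    masks/class rasters require nearest neighbor."""
    if target_cell <= 0:
        raise ValueError("target cell size must be > 0")
    if method not in ("bilinear", "nearest"):
        raise ValueError(f"unknown resampling method {method!r}")
    if raster.categorical and method == "bilinear":
        raise ValueError("categorical rasters (masks/classes) must be "
                         "resampled with method='nearest'")
    xmin, ymin, xmax, ymax = raster.extent
    n_cols = max(1, int(round((xmax - xmin) / target_cell)))
    n_rows = max(1, int(round((ymax - ymin) / target_cell)))
    xs = xmin + (np.arange(n_cols) + 0.5) * target_cell
    ys = ymax - (np.arange(n_rows) + 0.5) * target_cell
    Xn, Yn = np.meshgrid(xs, ys)
    vals = raster.sample(Xn.ravel(), Yn.ravel(), method=method)
    return Raster(vals.reshape(n_rows, n_cols), origin_x=xmin, origin_y=ymax,
                  cell_size=target_cell, nodata=raster.nodata,
                  categorical=raster.categorical)


@dataclass
class TerrainStack:
    """All derived environmental rasters on one grid."""

    savi: Raster
    elevation: Raster
    slope: Raster
    aspect: Raster
    aspect_class: Raster
    northness: Raster
    eastness: Raster

    def rugosity(self, region: Polygon) -> float:
        return acr_rugosity(self.elevation, region)


def build_terrain_stack(bundle, L: float = 0.5) -> TerrainStack:
    """Derive the full covariate stack from a landscape bundle.

    SAVI comes from the NIR/Red bands when present, else the bundle's
    vegetation index is used directly (already SAVI-like and water-masked).
    """
    if bundle.nir is not None and bundle.red is not None:
        savi = compute_savi(bundle.nir, bundle.red, L=L,
                            water_mask=bundle.water_mask)
    else:
        savi = bundle.veg_index
    slope, aspect = slope_aspect(bundle.dem)
    cls, northness, eastness = aspect_features(aspect)
    return TerrainStack(savi=savi, elevation=bundle.dem, slope=slope,
                        aspect=aspect, aspect_class=cls,
                        northness=northness, eastness=eastness)
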