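"""Covariate extraction, standardization, and collinearity pruning.

Two extraction designs: zonal statistics over polygons (observed and random
home ranges, the residency design) and circular buffers around telemetry
fixes whose radius matches the Argos error class (the relocation design).
Membership is cell-center-in-polygon; nodata cells are excluded. Covariates
are standardized (pooled over used and available units) and pruned so no
pair of retained variables has |Spearman rho| above 0.7, keeping the
higher-priority (more biologically relevant) variable of each correlated
set.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import shapely
from scipy import stats

from .raster import Raster

__all__ = [
    "BUFFER_RADIUS_M",
    "zonal_stats",
    "buffer_stats",
    "standardize",
    "destandardize",
    "prune_correlated",
    "residency_row",
]

#: Buffer radius (m) per Argos class for covariate extraction.
BUFFER_RADIUS_M = {"3": 250.0, "2": 500.0, "1": 1500.0, "A": 1500.0}


def _cells_in_polygon(raster: Raster, polygon) -> np.ndarray:
    """Values of cells whose centers fall inside the polygon (nodata
    dropped)."""
    xmin, ymin, xmax, ymax = polygon.bounds
    xs, ys = raster.x_centers, raster.y_centers
    jj = np.nonzero((xs >= xmin - raster.cell_size)
                    & (xs <= xmax + raster.cell_size))[0]
    ii = np.nonzero((ys >= ymin - raster.cell_size)
                    & (ys <= ymax + raster.cell_size))[0]
    if len(ii) == 0 or len(jj) == 0:
        return np.empty(0)
    X, Y = np.meshgrid(xs[jj], ys[ii])
    sub = raster.values[np.ix_(ii, jj)]
    inside = shapely.contains_xy(polygon, X.ravel(), Y.ravel())
    vals = sub.ravel()[inside]
    return vals[np.isfinite(vals)]


def zonal_stats(raster: Raster, polygon, which=("mean", "sd"),
                categories=None) -> dict:
    """Statistics over cells whose centers lie inside the polygon.

    ``which`` may contain 'mean', 'sd' (population) and/or 'proportions'
    (requires ``categories``: category codes mapped to labels). Raises on
    zero covered cells.
    """
    vals = _cells_in_polygon(raster, polygon)
    if vals.size == 0:
        raise ValueError("polygon covers no valid raster cells")
    out = {}
    if "mean" in which:
        out["mean"] = float(vals.mean())
    if "sd" in which:
        out["sd"] = float(vals.std(ddof=0))
    if "proportions" in which:
        if not categories:
            raise ValueError("'proportions' needs a categories mapping")
        n = vals.size
        for code, label in categories.items():
            out[f"prop_{label}"] = float((vals == code).sum() / n)
    return out


def buffer_stats(raster: Raster, x: float, y: float, argos_class: str,
                 radius_map: dict | None = None,
                 which=("mean", "sd")) -> dict:
    """Statistics in a circular buffer whose radius matches the fix's Argos
    error class (class A has no accuracy estimate and gets the widest,
    1500 m, radius)."""
    radius_map = BUFFER_RADIUS_M if radius_map is None else radius_map
    cls = str(argos_class)
    if cls not in radius_map:
        raise ValueError(f"no buffer radius for Argos class {cls!r}")
    r = radius_map[cls]
    # exact circle membership on the bounding-box subgrid (cell centers)
    xs, ys = raster.x_centers, raster.y_centers
    jj = np.nonzero((xs >= x - r) & (xs <= x + r))[0]
    ii = np.nonzero((ys >= y - r) & (ys <= y + r))[0]
    if len(ii) == 0 or len(jj) == 0:
        raise ValueError("buffer covers no raster cells")
    X, Y = np.meshgrid(xs[jj], ys[ii])
    sub = raster.values[np.ix_(ii, jj)]
    inside = (X - x) ** 2 + (Y - y) ** 2 <= r * r
    vals = sub[inside]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("buffer covers no valid raster cells")
    out = {}
    if "mean" in which:
        out["mean"] = float(vals.mean())
    if "sd" in which:
        out["sd"] = float(vals.std(ddof=0))
    out["radius_m"] = float(r)
    return out


def standardize(table: pd.DataFrame, columns, ddof: int = 1
                ) -> tuple[pd.DataFrame, dict]:
    """Center and scale columns to mean 0, sd 1 (sample sd by default),
    pooled over all rows. Returns the transformed table and per-column
    (mean, sd) metadata for back-transformation of effect sizes."""
    if len(table) < 2:
        raise ValueError("need at least 2 rows to standardize")
    out = table.copy()
    meta = {}
    for col in columns:
        x = table[col].to_numpy(dtype=float)
        m, s = float(np.mean(x)), float(np.std(x, ddof=ddof))
        if s == 0 or not np.isfinite(s):
            raise ValueError(f"column {col!r} has zero variance")
        out[col] = (x - m) / s
        meta[col] = {"mean": m, "sd": s}
    return out, meta


def destandardize(table: pd.DataFrame, meta: dict) -> pd.DataFrame:
    out = table.copy()
    for col, ms in meta.items():
        if col in out.columns:
            out[col] = out[col] * ms["sd"] + ms["mean"]
    return out


def prune_correlated(table: pd.DataFrame, priority: list[str],
                     threshold: float = 0.7):
    """Greedy Spearman pruning.

    Variables are scanned in priority order (most biologically relevant
    first); one is dropped when its |Spearman rho| with any already-kept
    variable strictly exceeds ``threshold``. Returns kept names and a
    report of all pairwise correlations with the drop decisions.
    """
    missing = [c for c in priority if c not in table.columns]
    if missing:
        raise ValueError(f"priority list names absent columns: {missing}")
    if len(priority) == 1:
        rho_mat = np.ones((1, 1))
    elif len(priority) == 2:
        r = stats.spearmanr(table[priority[0]], table[priority[1]])[0]
        rho_mat = np.array([[1.0, r], [r, 1.0]])
    else:
        rho_mat = stats.spearmanr(table[priority].to_numpy())[0]
    rho = pd.DataFrame(rho_mat, index=priority, columns=priority)
    kept: list[str] = []
    dropped: dict[str, str] = {}
    for var in priority:
        clash = [k for k in kept if abs(rho.loc[var, k]) > threshold]
        if clash:
            dropped[var] = clash[0]
        else:
            kept.append(var)
    report = {"spearman": rho, "dropped": dropped, "threshold": threshold}
    return kept, report


def residency_row(stack, polygon, rugosity: bool = True) -> dict:
    """Extract the residency-design covariates of one home-range polygon:
    mean/sd SAVI, mean elevation, mean slope, ACR rugosity, and the
    proportion of the range in each aspect class (flat cells excluded)."""
    from .terrain import acr_rugosity

    savi = zonal_stats(stack.savi, polygon)
    row = {
        "SAVI_mean": savi["mean"],
        "SAVI_sd": savi["sd"],
        "Elevation_mean": zonal_stats(stack.elevation, polygon,
                                      ("mean",))["mean"],
        "Slope_mean": zonal_stats(stack.slope, polygon, ("mean",))["mean"],
    }
    if rugosity:
        row["Rugosity"] = acr_rugosity(stack.elevation, polygon)
    cats = {0.0: "North", 1.0: "East", 2.0: "South", 3.0: "West"}
    try:
        props = zonal_stats(stack.aspect_class, polygon, ("proportions",),
                            categories=cats)
        row.update({k.replace("prop_", ""): v for k, v in props.items()})
    except ValueError:
        warnings.warn("home range covers no non-flat cells; aspect "
                      "proportions set to 0")
        row.update({v: 0.0 for v in cats.values()})
    return row
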