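"""Lightweight georegistered grid container.

All coordinates live in a projected plane in meters. Row 0 is the northern
edge of the grid; ``origin_x``/``origin_y`` locate the north-west corner.
Nodata cells are held as NaN in memory and serialized with an explicit
sentinel. On disk rasters are ESRI ASCII grids (plain text), which every
GIS reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = ["Raster"]


@dataclass
class Raster:
    """A single-band raster on a regular grid.

    Parameters
    ----------
    values
        2-D float array; NaN marks nodata. Row 0 is the northern row.
    origin_x, origin_y
        Coordinates (m) of the north-west corner of the grid.
    cell_size
        Cell edge length in meters (> 0).
    nodata
        Sentinel written to disk in place of NaN.
    categorical
        True for masks/class rasters; guards against bilinear resampling.
    """

    values: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    nodata: float = -9999.0
    categorical: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("raster must have at least one row and column")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size + np.isnan(self.values).sum() != self.values.size:
            raise ValueError("raster values must be finite or NaN (nodata)")

    # -- geometry -----------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer grid edges."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        """Cell-center y, descending (row 0 is the northern row)."""
        return self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (X, Y) of all cell centers, shaped like ``values``."""
        return np.meshgrid(self.x_centers, self.y_centers)

    def copy_with(self, values: np.ndarray, **kw) -> "Raster":
        """New raster on the same grid with different values."""
        return replace(self, values=np.asarray(values, dtype=float), **kw)

    # -- sampling -----------------------------------------------------------
    def rowcol(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Fractional (row, col) of points; integer part indexes the cell."""
        col = (np.asarray(x, dtype=float) - self.origin_x) / self.cell_size
        row = (self.origin_y - np.asarray(y, dtype=float)) / self.cell_size
        return row, col

    def sample(self, x, y, method: str = "bilinear") -> np.ndarray:
        """Sample values at point coordinates.

        ``bilinear`` interpolates between cell centers, ``nearest`` picks the
        containing cell. Points outside the grid return NaN.
        """
        row, col = self.rowcol(x, y)
        row = np.atleast_1d(row)
        col = np.atleast_1d(col)
        outside = (row < 0) | (row > self.n_rows) | (col < 0) \
            | (col > self.n_cols)
        # points within the outer half-cell ring take the edge cell's value
        coords = np.vstack([np.clip(row - 0.5, 0, self.n_rows - 1),
                            np.clip(col - 0.5, 0, self.n_cols - 1)])
        if method == "bilinear":
            order = 1
        elif method == "nearest":
            order = 0
        else:
            raise ValueError(f"unknown sampling method {method!r}")
        out = map_coordinates(self.values, coords, order=order,
                              mode="nearest")
        out[outside] = np.nan
        return out if np.ndim(x) else float(out[0])

    # -- text I/O -----------------------------------------------------------
    def write_ascii(self, path: str | Path, fmt: str = "%.6g") -> None:
        """Write as an ESRI ASCII grid (plain text)."""
        path = Path(path)
        vals = np.where(np.isnan(self.values), self.nodata, self.values)
        xll = self.origin_x
        yll = self.origin_y - self.n_rows * self.cell_size
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {xll!r}\n"
            f"yllcorner {yll!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        with path.open("w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt=fmt)

    @classmethod
    def read_ascii(cls, path: str | Path, categorical: bool = False) -> "Raster":
        path = Path(path)
        header: dict[str, float] = {}
        with path.open() as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            vals = np.loadtxt(fh)
        vals = np.atleast_2d(vals)
        nodata = header.get("nodata_value", -9999.0)
        vals = np.where(vals == nodata, np.nan, vals)
        cs = header["cellsize"]
        return cls(
            values=vals,
            origin_x=header["xllcorner"],
            origin_y=header["yllcorner"] + vals.shape[0] * cs,
            cell_size=cs,
            nodata=nodata,
            categorical=categorical,
        )

    def same_grid(self, other: "Raster", tol: float = 1e-6) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.origin_x - other.origin_x) < tol
            and abs(self.origin_y - other.origin_y) < tol
            and abs(self.cell_size - other.cell_size) < tol
        )
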