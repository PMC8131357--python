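"""Plain-text gridded covariate surfaces (ESRI ASCII grid dialect).

Grids carry landscape covariates (total fertiliser application rate,
forest-cover fraction) on a regular lon/lat raster, 5 arc-minutes in the
study design. Values are stored row-major from the north-west corner, the
convention of the ESRI ASCII format.

Cell lookup convention (coarse cells vs point sites, so it must be exact):
cells are half-open, [x, x+cellsize) in longitude and [y, y+cellsize) in
latitude; sites lying on the eastern or southern outer boundary of the
extent are mapped into the last cell, so the closed outer boundary of the
grid is usable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["CovariateGrid", "read_ascii_grid", "sum_grids"]


@dataclass
class CovariateGrid:
    values: np.ndarray        # (nrows, ncols), row 0 = northernmost
    xllcorner: float
    yllcorner: float
    cellsize: float           # decimal degrees
    nodata: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax)."""
        return (self.xllcorner, self.xllcorner + self.ncols * self.cellsize,
                self.yllcorner, self.yllcorner + self.nrows * self.cellsize)

    def cell_index(self, lon, lat):
        """Row/col of the cell containing each point; -1 where outside."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        xmin, xmax, ymin, ymax = self.extent
        inside = (lon >= xmin) & (lon <= xmax) & (lat >= ymin) & (lat <= ymax)
        col = np.floor((lon - xmin) / self.cellsize).astype(int)
        row_s = np.floor((lat - ymin) / self.cellsize).astype(int)
        # points on the outer east/north boundary fall into the last cell
        col = np.clip(col, 0, self.ncols - 1)
        row_s = np.clip(row_s, 0, self.nrows - 1)
        row = self.nrows - 1 - row_s
        row = np.where(inside, row, -1)
        col = np.where(inside, col, -1)
        return row, col

    def extract(self, lon, lat) -> np.ndarray:
        """Cell values at point locations; NaN outside extent or at NODATA."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        row, col = self.cell_index(lon, lat)
        out = np.full(lon.shape, np.nan)
        ok = row >= 0
        if not np.all(ok):
            warnings.warn(f"{int((~ok).sum())} site(s) outside grid extent; "
                          "value set to missing")
        vals = self.values[row[ok], col[ok]]
        vals = np.where(np.isclose(vals, self.nodata), np.nan, vals)
        out[ok] = vals
        return out

    def write_ascii(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.xllcorner!r}\n")
            fh.write(f"yllcorner {self.yllcorner!r}\n")
            fh.write(f"cellsize {self.cellsize!r}\n")
            fh.write(f"NODATA_value {self.nodata!r}\n")
            for r in range(self.nrows):
                fh.write(" ".join(repr(float(v)) for v in self.values[r]) + "\n")


def read_ascii_grid(path) -> CovariateGrid:
    """Read an ESRI ASCII grid written by :meth:`CovariateGrid.write_ascii`."""
    header = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    values = np.array(rows)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("grid body does not match declared nrows/ncols")
    return CovariateGrid(values=values,
                         xllcorner=header["xllcorner"],
                         yllcorner=header["yllcorner"],
                         cellsize=header["cellsize"],
                         nodata=header.get("nodata_value", -9999.0))


def sum_grids(grids) -> CovariateGrid:
    """Cell-wise sum of aligned grids (NODATA in any layer stays NODATA)."""
    grids = list(grids)
    base = grids[0]
    for g in grids[1:]:
        if (g.values.shape != base.values.shape
                or not np.isclose(g.xllcorner, base.xllcorner)
                or not np.isclose(g.yllcorner, base.yllcorner)
                or not np.isclose(g.cellsize, base.cellsize)):
            raise ValueError("grids are not aligned")
    stack = np.array([np.where(np.isclose(g.values, g.nodata), np.nan, g.values)
                      for g in grids])
    total = stack.sum(axis=0)
    out = np.where(np.isnan(total), base.nodata, total)
    return CovariateGrid(values=out, xllcorner=base.xllcorner,
                         yllcorner=base.yllcorner, cellsize=base.cellsize,
                         nodata=base.nodata)
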