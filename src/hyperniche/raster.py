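"""Gridded multilayer environments on a geographic lon/lat grid.

Rasters are stored and exchanged as ESRI ASCII grids (``.asc``): a
six-line header (ncols, nrows, xllcorner, yllcorner, cellsize,
NODATA_value) followed by rows of whitespace-separated values, north row
first.  The format is plain text, universally readable by GIS software,
and sufficient for the square-cell lon/lat grids this package works on.

Grid conventions
----------------
* Row 0 is the northernmost row; column 0 the westernmost column.
* Cells are half-open: a record at longitude ``lon`` falls in column
  ``floor((lon - west) / cellsize)``; analogous for latitude measured
  from the south edge.  Records exactly on the global east or north edge
  are assigned to the last column / top row so every point of the closed
  bounding box maps to some cell.
* The nodata mask is harmonized across layers: a cell is nodata if it is
  nodata in any layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GridMismatchError

NODATA = -9999.0

__all__ = [
    "EnvRasterStack",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_raster_stack",
]


def read_ascii_grid(path):
    """Read one ESRI ASCII grid.

    Returns ``(values, west, south, cellsize, nodata)`` with ``values``
    a (nrows, ncols) float array, north row first, nodata cells as NaN.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0][0].isalpha():
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    required = {"ncols", "nrows", "cellsize"}
    if not required <= header.keys():
        raise OSError(f"{path}: not an ESRI ASCII grid (missing header keys)")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    if "xllcorner" in header:
        west = header["xllcorner"]
        south = header["yllcorner"]
    else:  # xllcenter variant
        west = header["xllcenter"] - header["cellsize"] / 2
        south = header["yllcenter"] - header["cellsize"] / 2
    nodata = header.get("nodata_value", NODATA)
    values = np.loadtxt(lines[n_header:], dtype=float).reshape(nrows, ncols)
    values[values == nodata] = np.nan
    return values, west, south, header["cellsize"], nodata


def write_ascii_grid(path, values, west, south, cellsize, nodata=NODATA):
    """Write a (nrows, ncols) array (north row first, NaN = nodata)."""
    values = np.asarray(values, dtype=float)
    nrows, ncols = values.shape
    out = np.where(np.isnan(values), nodata, values)
    with open(path, "w") as fh:
        fh.write(
            f"ncols {ncols}\nnrows {nrows}\n"
            f"xllcorner {west:.10g}\nyllcorner {south:.10g}\n"
            f"cellsize {cellsize:.10g}\nNODATA_value {nodata:.10g}\n"
        )
        np.savetxt(fh, out, fmt="%.10g")


@dataclass
class EnvRasterStack:
    """Multilayer environment on a shared lon/lat grid.

    Attributes
    ----------
    names : list of str
        One name per layer, in column order of every derived matrix.
    values : ndarray, shape (nlayers, nrows, ncols)
        Layer grids, row 0 = north.  Nodata cells hold NaN.
    west, north : float
        Outer edges of the grid, in degrees.
    cellsize : float
        Square cell size in degrees (> 0).
    nodata_mask : ndarray of bool, shape (nrows, ncols)
        True where a cell is nodata in any layer (harmonized).
    """

    names: list
    values: np.ndarray
    west: float
    north: float
    cellsize: float
    nodata_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise GridMismatchError("values must be (nlayers, nrows, ncols)")
        if len(self.names) != self.values.shape[0]:
            raise GridMismatchError("one name per layer required")
        if self.cellsize <= 0:
            raise GridMismatchError("cellsize must be > 0")
        nan_mask = np.isnan(self.values).any(axis=0)
        if self.nodata_mask is None:
            self.nodata_mask = nan_mask
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool) | nan_mask
        # keep layers consistent with the harmonized mask
        self.values[:, self.nodata_mask] = np.nan

    # --- geometry -----------------------------------------------------
    @property
    def nlayers(self):
        return self.values.shape[0]

    @property
    def nrows(self):
        return self.values.shape[1]

    @property
    def ncols(self):
        return self.values.shape[2]

    @property
    def east(self):
        return self.west + self.ncols * self.cellsize

    @property
    def south(self):
        return self.north - self.nrows * self.cellsize

    @property
    def lons(self):
        """Cell-center longitudes, west to east."""
        return self.west + (np.arange(self.ncols) + 0.5) * self.cellsize

    @property
    def lats(self):
        """Cell-center latitudes, north to south (row order)."""
        return self.north - (np.arange(self.nrows) + 0.5) * self.cellsize

    def cell_index(self, lon, lat):
        """Map lon/lat arrays to (row, col); -1 where outside the grid.

        Half-open cells [west, east) x [south, north); points exactly on
        the global east/north edge map to the last column / top row.
        """
        scalar = np.isscalar(lon) or (np.ndim(lon) == 0)
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        col = np.floor((lon - self.west) / self.cellsize).astype(int)
        row_s = np.floor((lat - self.south) / self.cellsize).astype(int)
        col[lon == self.east] = self.ncols - 1
        row_s[lat == self.north] = self.nrows - 1
        row = self.nrows - 1 - row_s
        outside = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        row = np.where(outside, -1, row)
        col = np.where(outside, -1, col)
        if scalar:
            return int(row[0]), int(col[0])
        return row, col

    def cell_centers(self, rows, cols):
        """Lon/lat of cell centers for index arrays."""
        lon = self.west + (np.asarray(cols) + 0.5) * self.cellsize
        lat = self.north - (np.asarray(rows) + 0.5) * self.cellsize
        return lon, lat

    # --- value access -------------------------------------------------
    def valid_mask(self, extra_mask=None):
        m = ~self.nodata_mask
        if extra_mask is not None:
            m = m & np.asarray(extra_mask, dtype=bool)
        return m

    def cell_matrix(self, mask=None):
        """Environment matrix of (masked) valid cells.

        Returns a DataFrame (columns = layer names) whose index is the
        flat cell index ``row * ncols + col``, plus the (rows, cols)
        arrays in the same order.
        """
        m = self.valid_mask(mask)
        rows, cols = np.nonzero(m)
        data = self.values[:, rows, cols].T
        idx = rows * self.ncols + cols
        df = pd.DataFrame(data, columns=list(self.names), index=idx)
        return df, rows, cols

    def layer_stats(self, ddof=1):
        """Per-layer mean and SD over valid cells (stack-wide z-space)."""
        flat = self.values.reshape(self.nlayers, -1)
        valid = ~self.nodata_mask.ravel()
        means = flat[:, valid].mean(axis=1)
        sds = flat[:, valid].std(axis=1, ddof=ddof)
        return means, sds

    def cell_z(self, mask=None):
        """Standardized (stack-wide mean/SD) env matrix of valid cells."""
        df, rows, cols = self.cell_matrix(mask)
        means, sds = self.layer_stats()
        z = (df.to_numpy() - means) / sds
        return pd.DataFrame(z, columns=df.columns, index=df.index), rows, cols

    # --- I/O ----------------------------------------------------------
    def write(self, directory, prefix=""):
        """Write one ``.asc`` per layer; returns the paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, name in enumerate(self.names):
            p = directory / f"{prefix}{name}.asc"
            write_ascii_grid(p, self.values[i], self.west, self.south, self.cellsize)
            paths.append(p)
        return paths


def read_raster_stack(paths) -> EnvRasterStack:
    """Read ≥1 single-layer ASCII grids into a stack with a harmonized mask.

    Layer names are the file stems.  All layers must share shape and
    georeference; the first mismatching layer is named in the error.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise OSError("no raster paths given")
    layers, names = [], []
    ref = None
    for p in paths:
        values, west, south, cellsize, _ = read_ascii_grid(p)
        geo = (values.shape, round(west, 9), round(south, 9), round(cellsize, 9))
        if ref is None:
            ref = geo
            ref_west, ref_south, ref_cs = west, south, cellsize
        elif geo != ref:
            raise GridMismatchError(
                f"layer '{p.name}' grid {geo} does not match first layer {ref}"
            )
        layers.append(values)
        names.append(p.stem)
    arr = np.stack(layers)
    nrows = arr.shape[1]
    north = ref_south + nrows * ref_cs
    return EnvRasterStack(names=names, values=arr, west=ref_west, north=north,
                          cellsize=ref_cs)
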