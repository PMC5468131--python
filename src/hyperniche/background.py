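"""Accessible-area backgrounds: great-circle buffers and random points.

The background of a group is the set of raster cells whose center lies
within a fixed great-circle radius (default 200 km) of the nearest
occurrence record - the "available climate space" the group could have
sampled.  Random background points (pseudo-absences) are drawn
uniformly over those cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigurationError, InfeasibleSamplingError
from .occurrences import OccurrenceSet
from .raster import EnvRasterStack, write_ascii_grid

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius

__all__ = ["BackgroundMask", "haversine_km", "buffer_mask",
           "sample_background", "EARTH_RADIUS_KM"]


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371.0088 km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon, dlat = lon2 - lon1, lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def _unit_xyz(lon, lat):
    lon, lat = np.radians(lon), np.radians(lat)
    return np.column_stack([np.cos(lat) * np.cos(lon),
                            np.cos(lat) * np.sin(lon),
                            np.sin(lat)])


@dataclass
class BackgroundMask:
    """Boolean cell mask aligned to a stack, with its provenance."""

    mask: np.ndarray
    groups: list
    radius_km: float

    @property
    def n_cells(self):
        return int(self.mask.sum())

    def write(self, path, stack: EnvRasterStack):
        grid = np.where(stack.nodata_mask, np.nan, self.mask.astype(float))
        write_ascii_grid(path, grid, stack.west, stack.south, stack.cellsize)


def buffer_mask(stack: EnvRasterStack, occ: OccurrenceSet,
                radius_km: float = 200.0) -> BackgroundMask:
    """Cells whose center is within ``radius_km`` of the nearest record.

    Distances are great-circle (haversine-equivalent): cell centers and
    records are mapped to the unit sphere and compared by chord length,
    which is monotone in the central angle, so the thresholding is
    exact.  Nodata cells are never included.
    """
    if len(occ) == 0:
        raise ConfigurationError("empty occurrence set")
    if radius_km <= 0:
        raise ConfigurationError("radius_km must be > 0")
    lon_grid, lat_grid = np.meshgrid(stack.lons, stack.lats)
    cells = _unit_xyz(lon_grid.ravel(), lat_grid.ravel())
    lon, lat = occ.lonlat()
    tree = cKDTree(_unit_xyz(lon, lat))
    dist_chord, _ = tree.query(cells, k=1)
    # chord <-> arc: chord = 2 sin(theta/2), arc = R * theta
    chord_max = 2.0 * np.sin(min(radius_km / EARTH_RADIUS_KM, np.pi) / 2.0)
    mask = (dist_chord <= chord_max).reshape(stack.nrows, stack.ncols)
    mask &= ~stack.nodata_mask
    return BackgroundMask(mask=mask, groups=occ.groups, radius_km=radius_km)


def sample_background(bg: BackgroundMask, stack: EnvRasterStack,
                      n: int = 1000, seed: int = None,
                      exclude_cells=None) -> OccurrenceSet:
    """Draw ``n`` background points at masked cell centers.

    Sampling is without replacement when the mask holds at least ``n``
    cells, with replacement otherwise; the branch taken is recorded in
    ``df.attrs['replacement']``.  ``exclude_cells`` (flat cell indices,
    e.g. presence cells) are removed from the pool first.
    """
    rows, cols = np.nonzero(bg.mask)
    if rows.size == 0:
        raise ConfigurationError("background mask is empty")
    if exclude_cells is not None:
        flat = rows * stack.ncols + cols
        keep = ~np.isin(flat, np.asarray(list(exclude_cells)))
        rows, cols = rows[keep], cols[keep]
        if rows.size == 0:
            raise InfeasibleSamplingError(n, 0, "background cells")
    rng = np.random.default_rng(seed)
    replace = n > rows.size
    pick = rng.choice(rows.size, size=n, replace=replace)
    lon, lat = stack.cell_centers(rows[pick], cols[pick])
    df = pd.DataFrame({
        "id": [f"bg_{i + 1:05d}" for i in range(n)],
        "lon": lon, "lat": lat, "group": "background",
    })
    out = OccurrenceSet(df)
    out.df.attrs["replacement"] = replace
    out.df.attrs["seed"] = seed
    return out
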