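"""Binning of occurrence records into hexagonal grid cells.

The grid itself lives in :mod:`phylohex.dggs`; this module turns a cleaned
occurrence table into a :class:`PresenceMatrix` — the cell x species
incidence structure (presence = at least one record) plus per-cell record
counts used by the redundancy index.  Presence is deliberately binary:
the diversity indices downstream are incidence-based.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import shapely

from . import dggs
from .dggs import (  # re-exported grid API  # noqa: F401
    cell_count,
    cell_to_latlon,
    cell_to_parent,
    cell_to_str,
    grid_stats,
    is_pentagon,
    latlon_to_cell,
    mean_cell_area_km2,
    str_to_cell,
)

DEFAULT_RESOLUTION = 4  # coarse enough for global work, fine for regional


class PresenceMatrix:
    """Cell x species incidence at a fixed grid resolution.

    Attributes
    ----------
    resolution : grid resolution of all cells
    cells : sorted uint64 cell ids
    species : sorted int64 species keys
    A : boolean incidence array, shape (n_cells, n_species)
    records : per-cell record counts (each >= cell richness)
    """

    def __init__(self, resolution, cells, species, A, records):
        self.resolution = int(resolution)
        self.cells = np.asarray(cells, dtype=np.uint64)
        self.species = np.asarray(species, dtype=np.int64)
        self.A = np.asarray(A, dtype=bool)
        self.records = np.asarray(records, dtype=np.int64)
        assert self.A.shape == (len(self.cells), len(self.species))
        assert len(self.records) == len(self.cells)
        if len(self.cells):
            assert (self.richness() >= 1).all(), "cell with no species"
            assert (self.records >= self.richness()).all(), "records < richness"
            assert (self.ranges() >= 1).all(), "species occupying no cell"

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def cell_strs(self) -> list[str]:
        return [dggs.cell_to_str(c) for c in self.cells]

    def richness(self) -> np.ndarray:
        return self.A.sum(axis=1)

    def ranges(self) -> np.ndarray:
        """Occupied-cell count per species (its range size in cells)."""
        return self.A.sum(axis=0)

    def cell_index(self, cell) -> int:
        if isinstance(cell, str):
            cell = dggs.str_to_cell(cell)
        idx = np.searchsorted(self.cells, np.uint64(cell))
        if idx >= len(self.cells) or self.cells[idx] != np.uint64(cell):
            raise KeyError(f"cell {dggs.cell_to_str(cell)} not in matrix")
        return int(idx)

    def species_set(self, cell) -> set:
        return set(self.species[self.A[self.cell_index(cell)]].tolist())

    def with_incidence(self, A_new: np.ndarray) -> "PresenceMatrix":
        """Same cells/species/records with a replaced incidence (null models)."""
        return PresenceMatrix(self.resolution, self.cells, self.species, A_new, self.records)

    def to_frame(self) -> pd.DataFrame:
        """Long-format incidence table (cell, species_key)."""
        ci, sj = np.nonzero(self.A)
        return pd.DataFrame(
            {
                "cell": [dggs.cell_to_str(c) for c in self.cells[ci]],
                "species_key": self.species[sj],
            }
        )


def bin_occurrences(table, resolution: int = DEFAULT_RESOLUTION) -> PresenceMatrix:
    """Aggregate occurrence records into grid cells at ``resolution``.

    A species is present in a cell when it has at least one record there;
    ``records`` counts every retained row, so that
    ``sum(records) == len(table)``.
    """
    df = table.data if hasattr(table, "data") else table
    if len(df) == 0:
        warnings.warn("binning an empty occurrence table")
        return PresenceMatrix(
            resolution,
            np.empty(0, dtype=np.uint64),
            np.empty(0, dtype=np.int64),
            np.empty((0, 0), dtype=bool),
            np.empty(0, dtype=np.int64),
        )
    ids = dggs.cells_from_latlon(
        df["latitude"].to_numpy(dtype=float),
        df["longitude"].to_numpy(dtype=float),
        resolution,
    )
    cells, cell_inv = np.unique(ids, return_inverse=True)
    species, sp_inv = np.unique(df["species_key"].to_numpy(dtype=np.int64), return_inverse=True)
    A = np.zeros((len(cells), len(species)), dtype=bool)
    A[cell_inv, sp_inv] = True
    records = np.bincount(cell_inv, minlength=len(cells)).astype(np.int64)
    return PresenceMatrix(resolution, cells, species, A, records)


# ---------------------------------------------------------------------------
# cell geometry for GIS export
# ---------------------------------------------------------------------------

_WORLD = shapely.box(-180.0, -90.0, 180.0, 90.0)


def cell_polygon(cell) -> shapely.Geometry:
    """Cell outline as a WGS84 shapely (Multi)Polygon.

    Cells crossing the antimeridian are split into valid parts with all
    longitudes in [-180, 180]; the two polar cells are closed over the pole.
    """
    if isinstance(cell, str):
        cell = dggs.str_to_cell(cell)
    latlon = dggs.cell_boundary(int(cell))
    lat = latlon[:, 0]
    lon = latlon[:, 1].copy()
    # unwrap longitudes into a continuous sequence
    for i in range(1, len(lon)):
        d = lon[i] - lon[i - 1]
        if d > 180:
            lon[i:] -= 360.0
        elif d < -180:
            lon[i:] += 360.0
    closing = lon[0] - lon[-1]
    winding = round(closing / 360.0) * 360.0
    if abs(winding) > 0:  # ring encircles a pole
        pole = 90.0 if np.mean(lat) > 0 else -90.0
        order = np.argsort(lon)
        lon, lat = lon[order], lat[order]
        ring = list(zip(lon, lat))
        ring += [(lon[-1], pole), (lon[0] - 1e-9, pole)]
        poly = shapely.Polygon([(x, y) for x, y in ring])
    else:
        poly = shapely.Polygon(list(zip(lon, lat)))
    if not poly.is_valid:
        poly = poly.buffer(0)
    lo, _, hi, _ = poly.bounds
    if lo >= -180.0 and hi <= 180.0:
        return poly
    parts = []
    for shift in (-360.0, 0.0, 360.0):
        shifted = shapely.transform(poly, lambda coords, s=shift: coords + np.array([s, 0.0]))
        piece = shapely.intersection(shifted, _WORLD)
        if not piece.is_empty:
            parts.append(piece)
    return shapely.union_all(parts)


def cell_geometry(cell):
    """Alias for :func:`cell_polygon` (the GIS-export entry point)."""
    return cell_polygon(cell)
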