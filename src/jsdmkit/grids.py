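"""Raster predictor stacks on a regular longitude/latitude lattice.

A :class:`PredictorGrid` holds one or more named single-band rasters that share
a common extent, cell size and missing-data mask.  Grids are stored row-major
from the north-west corner (row 0 is the northernmost row) and cell lookup uses
half-open intervals on cell edges, so every point strictly inside the extent
maps to exactly one cell.

Rasters are read and written as ESRI ASCII grids (``.asc``), a plain-text
georeferenced single-band format understood by every GIS.  Values are printed
with ``repr`` so float64 rasters round-trip bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

NODATA = -9999.0


class GridError(ValueError):
    """Raised for inconsistent grid definitions or out-of-grid lookups."""


@dataclass
class PredictorGrid:
    """Aligned stack of named predictor rasters.

    Parameters
    ----------
    names
        Layer names, in order.
    data
        Mapping from layer name to a ``(nrows, ncols)`` float array; row 0 is
        the northernmost row.
    west, south
        Coordinates of the south-west corner of the extent (degrees).
    cell_size
        Cell edge length in degrees.
    mask
        Boolean validity mask shared by all layers (True = valid cell).
    """

    names: list[str]
    data: dict[str, np.ndarray]
    west: float
    south: float
    cell_size: float
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.names:
            raise GridError("grid needs at least one layer")
        shapes = {self.data[n].shape for n in self.names}
        if len(shapes) != 1:
            raise GridError(f"layer shapes differ: {shapes}")
        if self.mask is None:
            self.mask = np.ones(next(iter(shapes)), dtype=bool)
        if self.mask.shape != next(iter(shapes)):
            raise GridError("mask shape does not match layers")
        if self.cell_size <= 0:
            raise GridError("cell_size must be positive")

    # -- geometry -----------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.mask.shape[0]

    @property
    def ncols(self) -> int:
        return self.mask.shape[1]

    @property
    def north(self) -> float:
        return self.south + self.nrows * self.cell_size

    @property
    def east(self) -> float:
        return self.west + self.ncols * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (lons, lats) of cell centers; lons has length ncols,
        lats has length nrows in row order (north to south)."""
        lons = self.west + (np.arange(self.ncols) + 0.5) * self.cell_size
        lats = self.north - (np.arange(self.nrows) + 0.5) * self.cell_size
        return lons, lats

    def rowcol(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) indices; half-open cell intervals.

        Points on the east/north outer edge are clamped into the last cell so
        the closed extent is fully covered.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if np.any(lon < self.west) or np.any(lon > self.east) or \
           np.any(lat < self.south) or np.any(lat > self.north):
            raise GridError("coordinates outside the grid extent")
        col = np.floor((lon - self.west) / self.cell_size).astype(int)
        row = np.floor((self.north - lat) / self.cell_size).astype(int)
        col = np.clip(col, 0, self.ncols - 1)
        row = np.clip(row, 0, self.nrows - 1)
        return row, col

    def is_valid(self, lon, lat) -> np.ndarray:
        row, col = self.rowcol(lon, lat)
        return self.mask[row, col]

    def values_at(self, lon, lat) -> pd.DataFrame:
        """Nearest-cell values of every layer at the given coordinates."""
        row, col = self.rowcol(lon, lat)
        return pd.DataFrame({n: self.data[n][row, col] for n in self.names})

    def valid_cell_table(self) -> pd.DataFrame:
        """DataFrame of all valid cells: lon, lat (centers), row, col."""
        rows, cols = np.nonzero(self.mask)
        lons, lats = self.cell_centers()
        return pd.DataFrame(
            {"lon": lons[cols], "lat": lats[rows], "row": rows, "col": cols}
        )

    # -- I/O ----------------------------------------------------------------
    def write_dir(self, path: str | Path) -> None:
        """Write one ``<layer>.asc`` per layer plus ``grid.json`` metadata."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name in self.names:
            arr = np.where(self.mask, self.data[name], NODATA)
            write_ascii_grid(path / f"{name}.asc", arr, self.west, self.south,
                             self.cell_size)
        (path / "grid.json").write_text(
            json.dumps({"names": self.names, "cell_size": self.cell_size}))

    @classmethod
    def read_dir(cls, path: str | Path) -> "PredictorGrid":
        path = Path(path)
        meta = json.loads((path / "grid.json").read_text())
        data, mask, west, south = {}, None, None, None
        for name in meta["names"]:
            arr, w, s, cs = read_ascii_grid(path / f"{name}.asc")
            if west is None:
                west, south = w, s
            lmask = arr != NODATA
            mask = lmask if mask is None else (mask & lmask)
            data[name] = arr
        return cls(names=list(meta["names"]), data=data, west=west,
                   south=south, cell_size=meta["cell_size"], mask=mask)


def write_ascii_grid(path: str | Path, values: np.ndarray, west: float,
                     south: float, cell_size: float) -> None:
    """Write a single 2-D array as an ESRI ASCII grid (row 0 = north)."""
    nrows, ncols = values.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {west!r}\n")
        fh.write(f"yllcorner {south!r}\n")
        fh.write(f"cellsize {cell_size!r}\n")
        fh.write(f"NODATA_value {NODATA!r}\n")
        for row in values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, float, float]:
    """Read an ESRI ASCII grid; returns (values, west, south, cell_size)."""
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = val
        values = np.loadtxt(fh, dtype=float, ndmin=2)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if values.shape != (nrows, ncols):
        raise GridError(f"{path}: body shape {values.shape} does not match "
                        f"header ({nrows}, {ncols})")
    return (values, float(header["xllcorner"]), float(header["yllcorner"]),
            float(header["cellsize"]))
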