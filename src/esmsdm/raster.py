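"""Lightweight single-band raster container with ESRI ASCII grid I/O.

A :class:`Raster` is a 2-D float array in which nodata cells hold NaN,
plus minimal georeferencing (lower-left corner and square cell size).
Row 0 of the array is the *top* row of the map, matching the ASCII grid
convention. A :class:`RasterStack` is an ordered collection of named,
grid-aligned rasters — the environmental feature space of the pipeline.

The ASCII grid (.asc) format is plain text and round-trips exactly at the
printed precision, which keeps every artifact of a run human-inspectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["GridSpec", "Raster", "RasterStack", "read_ascii", "write_ascii"]

_NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Georeferencing of a regular square-celled grid.

    ``xll``/``yll`` are the coordinates of the lower-left corner of the
    lower-left cell; ``cell_size`` is the side of a cell in map units
    (meters in this package's studies, 30 m by default).
    """

    n_rows: int
    n_cols: int
    xll: float = 0.0
    yll: float = 0.0
    cell_size: float = 30.0

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of the center of cell (row, col); row 0 on top."""
        x = self.xll + (col + 0.5) * self.cell_size
        y = self.yll + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """Containing cell of a point, with half-open intervals [x0, x0+res).

        Raises if the point falls outside the grid extent.
        """
        col = math.floor((x - self.xll) / self.cell_size)
        row = self.n_rows - 1 - math.floor((y - self.yll) / self.cell_size)
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise InvalidArgumentError(f"point ({x}, {y}) outside grid extent")
        return row, col


class Raster:
    """Single-band raster: float64 array with NaN nodata and a GridSpec."""

    def __init__(self, data: np.ndarray, grid: GridSpec | None = None):
        data = np.asarray(data, dtype=float)
        if data.ndim != 2:
            raise InvalidArgumentError("raster data must be 2-D")
        self.data = data
        self.grid = grid or GridSpec(*data.shape)
        if (self.grid.n_rows, self.grid.n_cols) != data.shape:
            raise InvalidArgumentError("grid spec does not match data shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        return np.isfinite(self.data)

    def values_at(self, xy: np.ndarray) -> np.ndarray:
        """Extract cell values at an (n, 2) array of map coordinates."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        out = np.empty(len(xy))
        for i, (x, y) in enumerate(xy):
            r, c = self.grid.cell_index(x, y)
            out[i] = self.data[r, c]
        return out

    def copy_with(self, data: np.ndarray) -> "Raster":
        return Raster(np.asarray(data, dtype=float), self.grid)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Raster(shape={self.shape}, valid={int(self.mask.sum())})"


class RasterStack:
    """Ordered, grid-aligned collection of named rasters."""

    def __init__(self, layers: Mapping[str, Raster]):
        if not layers:
            raise InvalidArgumentError("empty stack")
        self._layers: dict[str, Raster] = dict(layers)
        grids = {(r.grid.n_rows, r.grid.n_cols) for r in self._layers.values()}
        if len(grids) != 1:
            raise InvalidArgumentError("stack layers must share one grid")

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    @property
    def grid(self) -> GridSpec:
        return next(iter(self._layers.values())).grid

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.n_rows, self.grid.n_cols

    def __getitem__(self, name: str) -> Raster:
        return self._layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __iter__(self) -> Iterator[str]:
        return iter(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    def subset(self, names: Iterable[str]) -> "RasterStack":
        return RasterStack({n: self._layers[n] for n in names})

    def valid_mask(self, names: Iterable[str] | None = None) -> np.ndarray:
        """Cells where every requested layer holds data."""
        names = list(names) if names is not None else self.names
        m = np.ones(self.shape, dtype=bool)
        for n in names:
            m &= self._layers[n].mask
        return m

    def table_at(self, xy: np.ndarray) -> "np.ndarray":
        """(n_points, n_layers) array of values at map coordinates."""
        return np.column_stack([self._layers[n].values_at(xy) for n in self.names])

    def to_table(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to (valid_cell_values, flat_indices) over jointly valid cells."""
        m = self.valid_mask()
        idx = np.flatnonzero(m.ravel())
        vals = np.column_stack([self._layers[n].data.ravel()[idx] for n in self.names])
        return vals, idx

    def write_dir(self, path: str | Path) -> None:
        """Write one .asc file per layer into a directory."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, r in self._layers.items():
            write_ascii(r, path / f"{name}.asc")

    @classmethod
    def read_dir(cls, path: str | Path) -> "RasterStack":
        path = Path(path)
        files = sorted(path.glob("*.asc"))
        if not files:
            raise InvalidArgumentError(f"no .asc layers found in {path}")
        return cls({f.stem: read_ascii(f) for f in files})


def write_ascii(raster: Raster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid with explicit nodata."""
    g = raster.grid
    data = np.where(raster.mask, raster.data, _NODATA)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.xll:.6f}\n"
        f"yllcorner {g.yll:.6f}\n"
        f"cellsize {g.cell_size:.6f}\n"
        f"NODATA_value {_NODATA:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.8g")


def read_ascii(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nodata = header.get("nodata_value", _NODATA)
    data = np.where(data == nodata, np.nan, data)
    grid = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cell_size=header["cellsize"],
    )
    return Raster(data, grid)
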