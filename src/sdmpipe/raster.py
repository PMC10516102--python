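"""Gridded raster containers and plain-text (ESRI ASCII grid) I/O.

All spatial data in the package travels as :class:`RasterGrid` (one band)
or :class:`ClimateStack` (a named set of co-registered bands with a
scenario tag). Grids are north-up with square cells; inputs are assumed
co-registered, so no reprojection machinery exists here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "ClimateStack", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class RasterGrid:
    """A single-band raster: 2D values + geotransform + nodata.

    Parameters
    ----------
    values : ndarray, shape (rows, cols)
        Cell values. For float rasters NaN marks nodata.
    x0, y0 : float
        Coordinates of the *north-west corner* of the grid.
    cell_size : float
        Square cell edge length, in coordinate units.
    nodata : float, optional
        Sentinel used on disk; in memory NaN is canonical for floats.
    """

    values: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    cell_size: float = 1.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("RasterGrid values must be 2D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean array, True where the cell carries data."""
        v = self.values
        if np.issubdtype(v.dtype, np.floating):
            return ~np.isnan(v)
        return np.ones(v.shape, dtype=bool)

    def xy_of(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinates of (row, col) indices."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        x = self.x0 + (cols + 0.5) * self.cell_size
        y = self.y0 - (rows + 0.5) * self.cell_size
        return x, y

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) indices of the cells containing coordinates (x, y)."""
        x = np.asarray(x)
        y = np.asarray(y)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row = np.floor((self.y0 - y) / self.cell_size).astype(int)
        return row, col

    def with_values(self, values: np.ndarray) -> "RasterGrid":
        """A new grid sharing this grid's georeferencing."""
        return replace(self, values=np.asarray(values))

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.x0, other.x0)
            and np.isclose(self.y0, other.y0)
            and np.isclose(self.cell_size, other.cell_size)
        )

    def require_aligned(self, other: "RasterGrid", what: str = "raster") -> None:
        if not self.aligned_with(other):
            raise ValueError(
                f"{what} is not co-registered: shapes {self.shape} vs {other.shape}, "
                f"origins ({self.x0},{self.y0}) vs ({other.x0},{other.y0})"
            )


@dataclass
class ClimateStack:
    """Named, co-registered raster layers with a scenario tag."""

    layers: dict[str, RasterGrid] = field(default_factory=dict)
    scenario: str = "present"

    def __post_init__(self) -> None:
        grids = list(self.layers.values())
        for g in grids[1:]:
            grids[0].require_aligned(g, "stack layer")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def grid(self) -> RasterGrid:
        """Reference grid (first layer)."""
        return next(iter(self.layers.values()))

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def subset(self, names: list[str]) -> "ClimateStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"stack '{self.scenario}' is missing layers: {missing}")
        return ClimateStack({n: self.layers[n] for n in names}, scenario=self.scenario)

    def to_table(
        self, names: list[str] | None = None, mask: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flatten layers to a (cells, layers) matrix.

        Returns ``(X, rows, cols)`` where rows/cols index the cells kept:
        those inside `mask` (if given) and valid in every layer.
        """
        if names is None:
            names = self.names
        stack = self.subset(names)
        valid = np.ones(self.grid.shape, dtype=bool) if mask is None else np.asarray(mask, bool).copy()
        for g in stack.layers.values():
            valid &= g.valid_mask()
        rows, cols = np.nonzero(valid)
        X = np.column_stack([stack.layers[n].values[rows, cols] for n in names])
        return X, rows, cols

    def values_at(self, x: np.ndarray, y: np.ndarray, names: list[str] | None = None) -> np.ndarray:
        """Layer values at point coordinates (by containing cell)."""
        if names is None:
            names = self.names
        r, c = self.grid.cell_of(x, y)
        return np.column_stack([self.layers[n].values[r, c] for n in names])


def write_ascii_grid(grid: RasterGrid, path: str | Path) -> None:
    """Write a grid as an ESRI ASCII raster (plain text)."""
    path = Path(path)
    v = grid.values.astype(float)
    out = np.where(np.isnan(v), grid.nodata, v)
    header = (
        f"ncols {grid.cols}\n"
        f"nrows {grid.rows}\n"
        f"xllcorner {grid.x0!r}\n"
        f"yllcorner {grid.y0 - grid.rows * grid.cell_size!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII raster written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    nodata = header.get("nodata_value", -9999.0)
    values[values == nodata] = np.nan
    rows = int(header["nrows"])
    cell = header["cellsize"]
    return RasterGrid(
        values=values,
        x0=header["xllcorner"],
        y0=header["yllcorner"] + rows * cell,
        cell_size=cell,
        nodata=nodata,
    )
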