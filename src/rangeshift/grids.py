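"""Planar raster grids.

Every spatial object in the pipeline lives on a :class:`GridSpec`: a uniform,
axis-aligned cell lattice in local planar map units.  Rows are stored top-down
(row 0 is the northernmost row), matching the ESRI ASCII grid convention used
for on-disk exchange.  No reprojection or geodesic cell areas are supported:
areas are cell counts on the uniform lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = ["GridSpec", "Grid", "write_ascii_grid", "read_ascii_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster: extent, cell size and nodata sentinel.

    ``origin_x``/``origin_y`` are the coordinates of the *lower-left corner*
    of the grid (ESRI ``xllcorner``/``yllcorner``).
    """

    n_rows: int
    n_cols: int
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0
    nodata: float = -9999.0
    crs_label: str = "local-planar"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(
                f"grid dimensions must be positive, got {self.n_rows}x{self.n_cols}"
            )
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer grid edge."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    @property
    def diagonal(self) -> float:
        xmin, ymin, xmax, ymax = self.extent
        return float(np.hypot(xmax - xmin, ymax - ymin))

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y + (self.n_rows - row - 0.5) * self.cell_size
        return (x, y)

    def all_centers(self) -> np.ndarray:
        """(n_cells, 2) array of cell-center coordinates in row-major order."""
        rows, cols = np.indices(self.shape)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y + (self.n_rows - rows - 0.5) * self.cell_size
        return np.column_stack([x.ravel(), y.ravel()])

    def cells_of(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) point coordinates to (n, 2) integer (row, col) indices.

        Raises ``ValueError`` listing the offending point indices if any point
        falls outside the grid extent.
        """
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        xmin, ymin, xmax, ymax = self.extent
        inside = (
            (pts[:, 0] >= xmin)
            & (pts[:, 0] <= xmax)
            & (pts[:, 1] >= ymin)
            & (pts[:, 1] <= ymax)
        )
        if not np.all(inside):
            bad = np.flatnonzero(~inside).tolist()
            raise ValueError(f"points outside grid extent at indices {bad}")
        col = np.floor((pts[:, 0] - xmin) / self.cell_size).astype(int)
        row = self.n_rows - 1 - np.floor((pts[:, 1] - ymin) / self.cell_size).astype(int)
        # points exactly on the top/right edge belong to the outermost cell
        col = np.clip(col, 0, self.n_cols - 1)
        row = np.clip(row, 0, self.n_rows - 1)
        return np.column_stack([row, col])


@dataclass
class Grid:
    """A single-band raster: a 2-D array on a :class:`GridSpec`.

    Float grids mark nodata cells with NaN in memory; boolean and integer
    grids are fully valid.
    """

    spec: GridSpec
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.spec.shape:
            raise ValueError(
                f"data shape {self.data.shape} does not match spec {self.spec.shape}"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        if np.issubdtype(self.data.dtype, np.floating):
            return ~np.isnan(self.data)
        return np.ones(self.spec.shape, dtype=bool)

    def values(self) -> np.ndarray:
        """Flat array of values at valid cells, row-major order."""
        return self.data[self.valid_mask]

    def same_geometry(self, other: "Grid") -> bool:
        return self.spec == other.spec


def _require_same_spec(specs: Iterable[GridSpec]) -> GridSpec:
    specs = list(specs)
    first = specs[0]
    for s in specs[1:]:
        if s != first:
            raise ValueError("grids combined in one operation must share a GridSpec")
    return first


def write_ascii_grid(grid: Grid, path: str | Path) -> None:
    """Write a grid as an ESRI ASCII raster (.asc).

    Boolean grids are written as 0/1 integers; NaN cells as the nodata value.
    """
    spec = grid.spec
    data = grid.data
    if data.dtype == bool:
        out = data.astype(int).astype(float)
    else:
        out = data.astype(float).copy()
        out[np.isnan(out)] = spec.nodata
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.origin_x!r}\n"
        f"yllcorner {spec.origin_y!r}\n"
        f"cellsize {spec.cell_size!r}\n"
        f"NODATA_value {spec.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> Grid:
    """Read an ESRI ASCII raster; nodata cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    spec = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
    )
    data[data == spec.nodata] = np.nan
    return Grid(spec=spec, data=data)
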