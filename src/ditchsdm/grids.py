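"""Raster grid container and text-raster (ESRI ASCII) input/output.

All layers in the pipeline -- terrain models, land use, covariate and
probability surfaces, masks -- share one in-memory representation:
a :class:`Grid` holding a 2-D float array plus the georeferencing needed
to convert between (row, col) indices and projected metre coordinates.

Grid convention (used throughout the package): 0-based (row, col) with the
origin at the top-left corner; row index increases southward, column index
eastward; the centre of cell (i, j) sits at

    x = xllcorner + (j + 0.5) * cell_size
    y = yllcorner + (nrows - i - 0.5) * cell_size

Rasters are serialized as ESRI ASCII grids (``.asc``): a plain-text,
diff-friendly format every GIS reads, which keeps fixtures and outputs
inspectable without binary tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["Grid", "read_ascii_grid", "write_ascii_grid", "read_write_rasters"]

_DEFAULT_NODATA = -9999.0


@dataclass
class Grid:
    """A georeferenced single-band raster.

    Parameters
    ----------
    data
        2-D array of cell values (float64). ``nan`` marks nodata in memory.
    cell_size
        Cell edge length in metres (square cells).
    xllcorner, yllcorner
        Projected coordinates of the lower-left corner of the grid.
    nodata
        Value used to encode nodata on disk.
    """

    data: np.ndarray
    cell_size: float = 2.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata: float = _DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"Grid data must be 2-D, got shape {self.data.shape}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def cell_area(self) -> float:
        """Area of one cell in m2."""
        return self.cell_size**2

    def like(self, data: np.ndarray) -> "Grid":
        """A new grid with the same georeferencing but different values."""
        if np.asarray(data).shape != self.data.shape:
            raise ValueError("shape mismatch with template grid")
        return replace(self, data=np.asarray(data, dtype=np.float64).copy())

    def copy(self) -> "Grid":
        return replace(self, data=self.data.copy())

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Projected (x, y) of a cell centre."""
        nrows = self.data.shape[0]
        x = self.xllcorner + (col + 0.5) * self.cell_size
        y = self.yllcorner + (nrows - row - 0.5) * self.cell_size
        return x, y

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing projected point (x, y)."""
        nrows = self.data.shape[0]
        col = int(np.floor((x - self.xllcorner) / self.cell_size))
        row = int(nrows - 1 - np.floor((y - self.yllcorner) / self.cell_size))
        return row, col

    def aligned_with(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.isclose(self.xllcorner, other.xllcorner)
            and np.isclose(self.yllcorner, other.yllcorner)
        )

    def require_aligned(self, other: "Grid", name: str = "grid") -> None:
        if not self.aligned_with(other):
            raise ValueError(
                f"misaligned {name}: shape {self.shape} vs {other.shape}, "
                f"cell {self.cell_size} vs {other.cell_size}, origin "
                f"({self.xllcorner},{self.yllcorner}) vs ({other.xllcorner},{other.yllcorner})"
            )


def write_ascii_grid(grid: Grid, path: str | Path) -> Path:
    """Write a grid as an ESRI ASCII raster (lossless for float64 via repr)."""
    path = Path(path)
    data = grid.data.copy()
    data[~np.isfinite(data)] = grid.nodata
    nrows, ncols = data.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {float(grid.xllcorner)!r}\n"
        f"yllcorner {float(grid.yllcorner)!r}\n"
        f"cellsize {float(grid.cell_size)!r}\n"
        f"NODATA_value {float(grid.nodata)!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in data:
            fh.write(" ".join(repr(float(v)) for v in row))  # shortest lossless repr
            fh.write("\n")
    return path


def read_ascii_grid(path: str | Path) -> Grid:
    """Read an ESRI ASCII raster; nodata cells become ``nan`` in memory."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.strip().partition(" ")
            key = key.lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(value)
                pos = fh.tell()
            else:  # optional NODATA line absent
                break
        fh.seek(pos)
        data = np.loadtxt(fh, dtype=np.float64, ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise ValueError(f"{path}: header declares {(nrows, ncols)}, body has {data.shape}")
    nodata = header.get("nodata_value", _DEFAULT_NODATA)
    data[data == nodata] = np.nan
    return Grid(
        data=data,
        cell_size=header["cellsize"],
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        nodata=nodata,
    )


def read_write_rasters(path: str | Path, grid: Grid | None = None) -> Grid | Path:
    """Single entry point for raster I/O: read when ``grid`` is None, else write."""
    if grid is None:
        return read_ascii_grid(path)
    return write_ascii_grid(grid, path)
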