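"""Regular-grid rasters and plain-text (ESRI ASCII) raster I/O.

All grids in a run share one projected, km-scale plane. Grids are north-up
and cell-centre registered: ``values[0, 0]`` is the north-west cell, and the
centre of the south-west cell sits at ``(xll + cell/2, yll + cell/2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Grid", "read_esri_ascii", "write_esri_ascii", "read_manifest", "write_manifest"]

_NODATA = -9999.0


@dataclass
class Grid:
    """A single-band raster on a regular grid.

    Parameters
    ----------
    name : str
        Band/covariate name.
    xll, yll : float
        Coordinates (km) of the lower-left *corner* of the grid.
    cell : float
        Cell size (km), square cells.
    values : ndarray, shape (n_rows, n_cols)
        Cell values, row 0 northernmost.
    """

    name: str
    xll: float
    yll: float
    cell: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be a 2-D array")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"grid {self.name!r} contains non-finite values")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.xll, other.xll)
            and np.isclose(self.yll, other.yll)
            and np.isclose(self.cell, other.cell)
        )

    def x_centers(self) -> np.ndarray:
        return self.xll + self.cell * (np.arange(self.n_cols) + 0.5)

    def y_centers(self) -> np.ndarray:
        """Northing of each row centre, row 0 northernmost."""
        top = self.yll + self.cell * self.n_rows
        return top - self.cell * (np.arange(self.n_rows) + 0.5)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (x, y) centre coordinates in row-major order."""
        xs, ys = np.meshgrid(self.x_centers(), self.y_centers())
        return xs.ravel(), ys.ravel()

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing each point; raises if outside."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        col = np.floor((x - self.xll) / self.cell).astype(int)
        row_from_bottom = np.floor((y - self.yll) / self.cell).astype(int)
        # points exactly on the top/right edge belong to the last cell
        col = np.where((x == self.xll + self.cell * self.n_cols), self.n_cols - 1, col)
        row_from_bottom = np.where(
            y == self.yll + self.cell * self.n_rows, self.n_rows - 1, row_from_bottom
        )
        if (
            np.any(col < 0)
            or np.any(col >= self.n_cols)
            or np.any(row_from_bottom < 0)
            or np.any(row_from_bottom >= self.n_rows)
        ):
            raise ValueError(f"point(s) outside grid {self.name!r}")
        row = self.n_rows - 1 - row_from_bottom
        return row, col

    def values_at(self, x, y) -> np.ndarray:
        """Value of the containing cell for each point (cell extraction rule)."""
        row, col = self.cell_index(x, y)
        return self.values[row, col]

    def with_values(self, values: np.ndarray, name: str | None = None) -> "Grid":
        return Grid(name or self.name, self.xll, self.yll, self.cell, np.asarray(values))


def write_esri_ascii(grid: Grid, path: str | Path) -> Path:
    """Write a grid as an ESRI ASCII raster (plain text)."""
    path = Path(path)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.xll!r}\n"
        f"yllcorner {grid.yll!r}\n"
        f"cellsize {grid.cell!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.values, fmt="%.8g")
    return path


def read_esri_ascii(path: str | Path, name: str | None = None) -> Grid:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    nodata = header.get("nodata_value", _NODATA)
    if np.any(values == nodata):
        raise ValueError(f"raster {path} contains NODATA cells, which are not supported")
    return Grid(
        name=name or path.stem,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cell=header["cellsize"],
        values=values,
    )


def write_manifest(names: list[str], paths: list[str | Path], path: str | Path) -> Path:
    """Sidecar manifest naming covariate rasters in test order, one per line."""
    path = Path(path)
    lines = [f"{n}\t{Path(p).name}" for n, p in zip(names, paths, strict=True)]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_manifest(path: str | Path) -> list[tuple[str, str]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if line.strip():
            name, fname = line.split("\t")
            out.append((name, fname))
    return out
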