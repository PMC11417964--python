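"""Plain-array climate grids with a JSON extent sidecar.

A grid is a dense 2-D float array plus an extent (xmin, xmax, ymin, ymax,
cell_size).  Row 0 is the northern (ymax) edge, matching the usual raster
convention.  Files are written as whitespace-delimited text next to a
``<name>.extent.json`` sidecar, so everything stays human-readable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class Extent:
    xmin: float
    xmax: float
    ymin: float
    ymax: float
    cell_size: float

    def to_dict(self):
        return {"xmin": self.xmin, "xmax": self.xmax, "ymin": self.ymin,
                "ymax": self.ymax, "cell_size": self.cell_size}


@dataclass
class Grid:
    values: np.ndarray  # (nrow, ncol)
    extent: Extent

    @property
    def shape(self):
        return self.values.shape

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing point (x, y)."""
        e = self.extent
        col = int((x - e.xmin) / e.cell_size)
        row = int((e.ymax - y) / e.cell_size)
        nrow, ncol = self.values.shape
        if not (0 <= row < nrow and 0 <= col < ncol):
            raise ValueError(f"point ({x}, {y}) outside grid extent")
        return row, col

    def value_at(self, x: float, y: float) -> float:
        r, c = self.cell_of(x, y)
        return float(self.values[r, c])

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        e = self.extent
        return (e.xmin + (col + 0.5) * e.cell_size,
                e.ymax - (row + 0.5) * e.cell_size)


def write_grid(grid: Grid, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, grid.values)
    sidecar = path.with_suffix(path.suffix + ".extent.json")
    sidecar.write_text(json.dumps(grid.extent.to_dict()))


def read_grid(path: str | Path) -> Grid:
    path = Path(path)
    values = np.atleast_2d(np.loadtxt(path))
    sidecar = path.with_suffix(path.suffix + ".extent.json")
    extent = Extent(**json.loads(sidecar.read_text()))
    return Grid(values=values, extent=extent)


def check_aligned(*grids: Grid) -> None:
    """Raise if grids differ in shape or extent."""
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape or g.extent.to_dict() != ref.extent.to_dict():
            raise ValueError("grid extent/shape mismatch")
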