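"""Regular 1-km raster grid and the PM2.5 concentration field container.

Coordinates are projected kilometres (UTM-like). Cells are squares; the
stored coordinate of a cell is its centre, values are cell means, and
arrays are row-major with y varying along axis 0 (row 0 = southernmost).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Grid", "ConcentrationField"]


@dataclass(frozen=True)
class Grid:
    """A regular square-cell grid in projected km coordinates.

    ``x0``/``y0`` are the centre of the lower-left (south-west) cell.
    """

    x0: float
    y0: float
    nx: int
    ny: int
    dx: float = 1.0  # km

    def __post_init__(self) -> None:
        if self.nx <= 0 or self.ny <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.dx <= 0:
            raise ValueError("cell size must be positive")

    @classmethod
    def from_extent(cls, width_km: float, height_km: float, dx: float = 1.0) -> "Grid":
        """Grid covering [0, width] x [0, height] with cells of size ``dx``."""
        nx = int(round(width_km / dx))
        ny = int(round(height_km / dx))
        return cls(x0=dx / 2.0, y0=dx / 2.0, nx=nx, ny=ny, dx=dx)

    @classmethod
    def centered(cls, halfwidth_km: float, dx: float = 1.0) -> "Grid":
        """Square grid centred on (0, 0), odd cell count, for recentred plumes."""
        n = 2 * int(round(halfwidth_km / dx)) + 1
        h = (n - 1) / 2.0 * dx
        return cls(x0=-h, y0=-h, nx=n, ny=n, dx=dx)

    @property
    def x(self) -> np.ndarray:
        return self.x0 + self.dx * np.arange(self.nx)

    @property
    def y(self) -> np.ndarray:
        return self.y0 + self.dx * np.arange(self.ny)

    @property
    def cell_area_km2(self) -> float:
        return self.dx * self.dx

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid's outer edges."""
        h = self.dx / 2.0
        return (
            self.x0 - h,
            self.y0 - h,
            self.x0 + self.dx * (self.nx - 1) + h,
            self.y0 + self.dx * (self.ny - 1) + h,
        )

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing the point; raises if outside."""
        col = int(np.floor((x - (self.x0 - self.dx / 2.0)) / self.dx))
        row = int(np.floor((y - (self.y0 - self.dx / 2.0)) / self.dx))
        if not (0 <= col < self.nx and 0 <= row < self.ny):
            raise IndexError(f"point ({x}, {y}) lies outside the grid")
        return row, col

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.bounds
        return xmin <= x <= xmax and ymin <= y <= ymax


@dataclass
class ConcentrationField:
    """A gridded PM2.5 surface (24-h mean, annual mean or period mean).

    Values are micrograms per cubic metre after station calibration and in
    arbitrary emission-proportional units before it.
    """

    grid: Grid
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.ny, self.grid.nx):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.ny}, {self.grid.nx})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("concentration field contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("concentration field contains negative values")

    @classmethod
    def zeros(cls, grid: Grid, label: str = "") -> "ConcentrationField":
        return cls(grid, np.zeros((grid.ny, grid.nx)), label)

    def value_at(self, x: float, y: float) -> float:
        row, col = self.grid.index_of(x, y)
        return float(self.values[row, col])

    def scaled(self, k: float, label: str | None = None) -> "ConcentrationField":
        return ConcentrationField(self.grid, self.values * k, label if label is not None else self.label)

    def total_mass(self, layer_depth_m: float = 1.0) -> float:
        """Domain integral value * cell_area * layer depth (SI: value/m3 * m3)."""
        return float(self.values.sum()) * self.grid.cell_area_km2 * 1.0e6 * layer_depth_m

    # --- I/O: CSV of (x, y, value) plus a JSON metadata sidecar ---------

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        xx, yy = np.meshgrid(self.grid.x, self.grid.y)
        df = pd.DataFrame(
            {"x_km": xx.ravel(), "y_km": yy.ravel(), "pm25": self.values.ravel()}
        )
        df.to_csv(path, index=False, float_format="%.17g")
        meta = {
            "x0": self.grid.x0,
            "y0": self.grid.y0,
            "nx": self.grid.nx,
            "ny": self.grid.ny,
            "dx": self.grid.dx,
            "label": self.label,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConcentrationField":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        grid = Grid(meta["x0"], meta["y0"], meta["nx"], meta["ny"], meta["dx"])
        df = pd.read_csv(path)
        values = df["pm25"].to_numpy().reshape(grid.ny, grid.nx)
        return cls(grid, values, meta.get("label", ""))
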