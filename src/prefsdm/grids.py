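"""Regular lattice geometry and latent surfaces.

The study window is a regular grid of square cells.  Cell values are stored
flat in row-major order with x varying fastest: the cell in column ``ix``
(along x) and row ``iy`` (along y) has flat index ``iy * nx + ix``.  Cell
centers sit at ``origin + (ix + 0.5, iy + 0.5) * cell_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import ArgumentError


@dataclass(frozen=True)
class GridGeometry:
    """A regular grid of square cells covering the study window."""

    nx: int
    ny: int
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.nx < 2 or self.ny < 2:
            raise ArgumentError(f"grid must be at least 2x2, got {self.nx}x{self.ny}")
        if not self.cell_size > 0:
            raise ArgumentError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    @property
    def width(self) -> float:
        return self.nx * self.cell_size

    @property
    def height(self) -> float:
        return self.ny * self.cell_size

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of cell-center coordinates, row-major x-fastest."""
        ix, iy = np.meshgrid(np.arange(self.nx), np.arange(self.ny))
        x = self.origin[0] + (ix.ravel() + 0.5) * self.cell_size
        y = self.origin[1] + (iy.ravel() + 0.5) * self.cell_size
        return np.column_stack([x, y])

    def flat_index(self, ix, iy):
        ix = np.asarray(ix)
        iy = np.asarray(iy)
        if np.any(ix < 0) or np.any(ix >= self.nx) or np.any(iy < 0) or np.any(iy >= self.ny):
            raise ArgumentError("cell index outside the grid")
        return iy * self.nx + ix

    def cell_of_coords(self, x, y):
        """Map real-valued coordinates to flat cell indices by floor division."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ix = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        iy = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        return self.flat_index(ix, iy)

    def expand(self, pad_cells: int) -> "GridGeometry":
        """Grid extended by ``pad_cells`` cells on every side."""
        if pad_cells < 0:
            raise ArgumentError("pad_cells must be >= 0")
        if pad_cells == 0:
            return self
        return GridGeometry(
            nx=self.nx + 2 * pad_cells,
            ny=self.ny + 2 * pad_cells,
            cell_size=self.cell_size,
            origin=(
                self.origin[0] - pad_cells * self.cell_size,
                self.origin[1] - pad_cells * self.cell_size,
            ),
        )

    def interior_of(self, extended: "GridGeometry", pad_cells: int) -> np.ndarray:
        """Flat indices, on ``extended``, of this grid's cells (selection map)."""
        ix, iy = np.meshgrid(np.arange(self.nx) + pad_cells, np.arange(self.ny) + pad_cells)
        return (iy * extended.nx + ix).ravel()


@dataclass
class LatentField:
    """A latent surface: one real value per grid cell (row-major, x fastest)."""

    grid: GridGeometry
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.grid.n_cells:
            raise ArgumentError(
                f"field has {self.values.size} values for a grid of {self.grid.n_cells} cells"
            )
        if not np.all(np.isfinite(self.values)):
            raise ArgumentError("latent field values must all be finite")

    def as_array(self) -> np.ndarray:
        """Values reshaped to (ny, nx) with row iy=0 at the south edge."""
        return self.values.reshape(self.grid.ny, self.grid.nx)


def as_surface(values, grid: GridGeometry, metadata: Optional[dict] = None) -> LatentField:
    return LatentField(grid=grid, values=np.asarray(values, dtype=float), metadata=metadata or {})
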