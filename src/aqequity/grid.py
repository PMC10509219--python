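"""Regular model grid.

Cells are squares of edge ``cell_km`` laid out row-major: cell id
``iy * nx + ix``.  Geometry is abstract planar kilometres (no projection);
everything downstream only needs centroid distances and cell areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError


@dataclass(frozen=True)
class Grid:
    nx: int
    ny: int
    cell_km: float = 1.0

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ConfigurationError(f"grid dimensions must be >= 1, got {self.nx}x{self.ny}")
        if self.cell_km <= 0:
            raise ConfigurationError(f"cell_km must be positive, got {self.cell_km}")

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def cell_area_km2(self) -> float:
        return self.cell_km ** 2

    def centroids(self) -> np.ndarray:
        """(n_cells, 2) array of cell-centre coordinates in km."""
        iy, ix = np.divmod(np.arange(self.n_cells), self.nx)
        return np.column_stack([(ix + 0.5) * self.cell_km, (iy + 0.5) * self.cell_km])

    def cell_at(self, x_km: float, y_km: float) -> int:
        """Cell id containing a point; points on upper edges clip inward."""
        ix = min(int(x_km / self.cell_km), self.nx - 1)
        iy = min(int(y_km / self.cell_km), self.ny - 1)
        if ix < 0 or iy < 0:
            raise ConfigurationError(f"point ({x_km}, {y_km}) outside grid")
        return iy * self.nx + ix

    def distance_matrix(self) -> np.ndarray:
        """Pairwise centroid distances (km), shape (n_cells, n_cells)."""
        c = self.centroids()
        diff = c[:, None, :] - c[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=2))
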