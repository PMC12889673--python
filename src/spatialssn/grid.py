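"""Regular 2D retinotopic grids.

Units of visual space are degrees of visual angle throughout.  Node
coordinates are centred on the stimulus centre: ``x_i = (i - (n-1)/2) * Δ``,
so for odd node counts one node sits exactly at (0°, 0°) while for even
counts the centre falls between nodes and "the centred unit" means the node
nearest to the origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np


@dataclass(frozen=True)
class RetinotopicGrid:
    """A regular ``n_y × n_x`` grid of units in retinotopic space.

    Parameters
    ----------
    n_x, n_y : int
        Number of nodes along the horizontal / vertical dimension (≥ 2).
    spacing : float
        Grid spacing Δ in degrees; each unit represents a Δ × Δ patch, and
        the area element Δ² converts kernel sums into integrals.
    """

    n_x: int
    n_y: int
    spacing: float

    def __post_init__(self) -> None:
        if self.n_x < 2 or self.n_y < 2:
            raise ValueError("grid needs at least 2 nodes along each axis")
        if not self.spacing > 0:
            raise ValueError("grid spacing must be positive")

    @property
    def n_nodes(self) -> int:
        return self.n_x * self.n_y

    @property
    def area_element(self) -> float:
        """Δ², the area represented by one node."""
        return self.spacing ** 2

    @cached_property
    def coords(self) -> np.ndarray:
        """(n_nodes, 2) array of (x, y) positions in degrees.

        Nodes are flattened row-major: index ``k = iy * n_x + ix``.
        """
        xs = (np.arange(self.n_x) - (self.n_x - 1) / 2.0) * self.spacing
        ys = (np.arange(self.n_y) - (self.n_y - 1) / 2.0) * self.spacing
        gx, gy = np.meshgrid(xs, ys)  # gy varies along rows
        return np.column_stack([gx.ravel(), gy.ravel()])

    @cached_property
    def sq_distance_matrix(self) -> np.ndarray:
        """(n_nodes, n_nodes) matrix of squared inter-node distances."""
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.einsum("ijk,ijk->ij", diff, diff)

    @cached_property
    def radii(self) -> np.ndarray:
        """Distance of each node from the stimulus centre (0°, 0°)."""
        return np.hypot(self.coords[:, 0], self.coords[:, 1])

    @cached_property
    def center_index(self) -> int:
        """Index of the node nearest to the stimulus centre."""
        return int(np.argmin(self.radii))

    def node_index(self, ix: int, iy: int) -> int:
        if not (0 <= ix < self.n_x and 0 <= iy < self.n_y):
            raise IndexError(f"node ({ix}, {iy}) outside {self.n_y}x{self.n_x} grid")
        return iy * self.n_x + ix

    def reshape(self, field: np.ndarray) -> np.ndarray:
        """Reshape a flat per-node field to (..., n_y, n_x)."""
        return np.asarray(field).reshape(*np.shape(field)[:-1], self.n_y, self.n_x)

    @property
    def extent(self) -> float:
        """Full width of the grid footprint in degrees (x dimension)."""
        return self.n_x * self.spacing
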