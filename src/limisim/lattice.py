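"""Toroidal square-lattice geometry and von Neumann neighbor queries.

The simulation field is a 2-D grid of cells with periodic (toroidal)
boundary conditions, so every cell has exactly four orthogonal neighbors
(the von Neumann neighborhood) and the lattice has no edge effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LatticeSpec", "von_neumann_neighbors", "neighbor_average", "neighbor_sum"]


@dataclass(frozen=True)
class LatticeSpec:
    """Dimensions of the toroidal simulation field.

    Both dimensions must be at least 3 so that a cell and its four
    neighbors are five distinct cells.
    """

    width: int = 20
    height: int = 20

    def __post_init__(self) -> None:
        if self.width < 3 or self.height < 3:
            raise ValueError(
                f"lattice must be at least 3x3, got {self.height}x{self.width}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def n_cells(self) -> int:
        return self.height * self.width


def von_neumann_neighbors(
    cell: tuple[int, int], lattice: LatticeSpec
) -> list[tuple[int, int]]:
    """Four orthogonal neighbors of ``cell`` with toroidal wraparound.

    Returned in (up, down, left, right) order with 0-based (row, col)
    coordinates.
    """
    r, c = cell
    h, w = lattice.height, lattice.width
    if not (0 <= r < h and 0 <= c < w):
        raise IndexError(f"cell {cell} outside {h}x{w} lattice")
    return [((r - 1) % h, c), ((r + 1) % h, c), (r, (c - 1) % w), (r, (c + 1) % w)]


def _check_shape(field: np.ndarray, lattice: LatticeSpec | None) -> None:
    if field.ndim != 2:
        raise ValueError(f"field must be 2-D, got shape {field.shape}")
    if lattice is not None and field.shape != lattice.shape:
        raise ValueError(f"field shape {field.shape} does not match lattice {lattice.shape}")


def neighbor_sum(field: np.ndarray, lattice: LatticeSpec | None = None) -> np.ndarray:
    """Per-cell sum of ``field`` over the four von Neumann neighbors."""
    _check_shape(field, lattice)
    return (
        (np.roll(field, 1, axis=0) + np.roll(field, -1, axis=0))
        + np.roll(field, 1, axis=1)
    ) + np.roll(field, -1, axis=1)


def neighbor_average(field: np.ndarray, lattice: LatticeSpec | None = None) -> np.ndarray:
    """Per-cell arithmetic mean of ``field`` over the four von Neumann neighbors.

    This is the juxtacrine coupling term: the ligand (or receptor) level a
    cell "sees" on the membranes of the cells it touches.
    """
    return 0.25 * neighbor_sum(field, lattice)
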