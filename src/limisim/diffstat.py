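"""The diff statistic: a z-score of PV-neighbor reporter levels.

At equilibrium, the mean (Ave) and population SD of the reporter are
computed over every cell *except* the PV cells and their von Neumann
neighbors.  Each PV-neighboring cell then gets

    diff = (R_neighbor - Ave) / SD

and a neighbor with diff strictly greater than the threshold (default 2)
is called a cholangiocyte.  The four neighbor diffs are averaged *before*
the log2 transform used in sweep color maps; a non-positive average or a
zero SD yields a sentinel (rendered as a cross) instead of a log2 value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import GridState, SimulationParams
from .lattice import von_neumann_neighbors

__all__ = ["DiffReport", "compute_diff", "classify_cholangiocytes",
           "SENTINEL_INFINITY", "SENTINEL_NEGATIVE"]

SENTINEL_INFINITY = "infinity"  # SD of the included cells is zero
SENTINEL_NEGATIVE = "negative"  # averaged diff is zero or negative


@dataclass
class DiffReport:
    """diff values of the PV-neighboring cells and their summary.

    ``log2_mean_diff`` is NaN exactly when ``sentinel`` is set.
    """

    ave: float
    sd: float
    neighbor_cells: tuple[tuple[int, int], ...]
    neighbor_diffs: np.ndarray
    mean_diff: float
    log2_mean_diff: float
    sentinel: str | None
    cholangiocyte_calls: np.ndarray

    def to_dict(self) -> dict:
        return {
            "ave": self.ave,
            "sd": self.sd,
            "neighbor_cells": [[int(r), int(c)] for r, c in self.neighbor_cells],
            "neighbor_diffs": [float(d) for d in self.neighbor_diffs],
            "mean_diff": float(self.mean_diff),
            "log2_mean_diff": None if self.sentinel else float(self.log2_mean_diff),
            "sentinel": self.sentinel,
            "cholangiocyte_calls": [bool(b) for b in self.cholangiocyte_calls],
        }


def pv_neighborhood(
    state: GridState, params: SimulationParams
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """PV-neighboring cells (row-major order) and the included-cell mask.

    Neighbors are the union of the PV cells' von Neumann neighborhoods
    minus the PV cells themselves; included cells are everything else.
    """
    pv_cells = [(int(r), int(c)) for r, c in np.argwhere(state.pv_mask)]
    neighbor_set: set[tuple[int, int]] = set()
    for cell in pv_cells:
        neighbor_set.update(von_neumann_neighbors(cell, params.lattice))
    neighbor_set -= set(pv_cells)
    neighbors = sorted(neighbor_set)
    included = ~state.pv_mask.copy()
    for (r, c) in neighbors:
        included[r, c] = False
    return neighbors, included


def compute_diff(state: GridState, params: SimulationParams) -> DiffReport:
    """Compute the diff report for an equilibrium state with PV cells."""
    state.validate(params)
    if not state.pv_mask.any():
        raise ValueError("diff statistic requires at least one PV cell")
    neighbors, included = pv_neighborhood(state, params)
    n_included = int(included.sum())
    if n_included < 2:
        raise ValueError(f"need at least 2 included cells, got {n_included}")

    values = state.R[included]
    ave = float(values.mean())
    sd = float(values.std())  # population SD
    rows = np.array([r for r, _ in neighbors])
    cols = np.array([c for _, c in neighbors])
    with np.errstate(divide="ignore", invalid="ignore"):
        diffs = (state.R[rows, cols] - ave) / sd

    if sd == 0.0:
        sentinel = SENTINEL_INFINITY
        mean_diff = float("inf")
        log2_mean = float("nan")
    else:
        mean_diff = float(diffs.mean())
        if mean_diff <= 0.0:
            sentinel = SENTINEL_NEGATIVE
            log2_mean = float("nan")
        else:
            sentinel = None
            log2_mean = float(np.log2(mean_diff))

    with np.errstate(invalid="ignore"):
        calls = diffs > params.diff_threshold
    return DiffReport(
        ave=ave,
        sd=sd,
        neighbor_cells=tuple(neighbors),
        neighbor_diffs=diffs,
        mean_diff=mean_diff,
        log2_mean_diff=log2_mean,
        sentinel=sentinel,
        cholangiocyte_calls=np.asarray(calls, dtype=bool),
    )


def classify_cholangiocytes(
    report: DiffReport, params: SimulationParams
) -> np.ndarray:
    """Boolean call per PV-neighboring cell: diff strictly above threshold."""
    with np.errstate(invalid="ignore"):
        return np.asarray(report.neighbor_diffs > params.diff_threshold, dtype=bool)
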