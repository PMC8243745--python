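"""Production-rate phase diagrams and one-dimensional sensitivity sweeps.

``sweep_2d`` maps the averaged-diff statistic (log2 scale) over a grid of
Notch and Delta production rates for one (m, n) panel — the phase diagram
separating disturbance-driven differentiation from its absence.
``sweep_1d`` varies one of the fixed constants while everything else
stays at base values.  Every sweep cell is a full pipeline run (random
initial state, one central PV cell, integrate to equilibrium, diff); cells
that yield a sentinel (zero SD or non-positive averaged diff) or fail to
converge carry a status marker instead of a number.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .dynamics import SimulationParams
from .pipeline import derive_seed, run_pipeline

__all__ = ["SweepGrid", "SweepPoint", "sweep_2d", "sweep_1d",
           "DEFAULT_AXIS", "DEFAULT_PANELS", "SWEEPABLE_1D"]

# log-spaced production-rate axis bracketing both worked cases (10 and 100)
DEFAULT_AXIS = tuple(np.logspace(0.0, 3.0, 10))
# (m, n) panels: feedback-strength and Hill exponents
DEFAULT_PANELS = ((1.0, 1.0), (1.0, 3.0), (2.0, 1.0), (2.0, 3.0))
# constants eligible for 1-D sensitivity sweeps
SWEEPABLE_1D = ("beta_R", "k_t", "k_c", "gamma", "gamma_R", "k_RS", "pv_delta", "dt")

STATUS_OK = "ok"
STATUS_NO_CONVERGENCE = "no-convergence"
_CSV_TOKENS = {"infinity": "CROSS", "negative": "CROSS",
               STATUS_NO_CONVERGENCE: "NOCONV"}


@dataclass
class SweepGrid:
    """Result matrix of a 2-D production-rate sweep for one (m, n) panel.

    ``log2`` holds log2(averaged diff) where defined and NaN on sentinel
    cells; ``status`` distinguishes 'ok', 'infinity', 'negative' and
    'no-convergence' (the latter keeps the capped-state value in ``log2``
    but renders as a cross).  Rows follow ``beta_N_values``, columns
    ``beta_D_values``.
    """

    beta_N_values: np.ndarray
    beta_D_values: np.ndarray
    m: float
    n: float
    log2: np.ndarray
    status: np.ndarray
    seeds: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        """Human-readable table: sentinel cells carry CROSS/NOCONV tokens."""
        body = np.empty(self.log2.shape, dtype=object)
        for idx in np.ndindex(*self.log2.shape):
            st = self.status[idx]
            body[idx] = self.log2[idx] if st == STATUS_OK else _CSV_TOKENS[st]
        return pd.DataFrame(
            body,
            index=pd.Index(self.beta_N_values, name="beta_N"),
            columns=pd.Index(self.beta_D_values, name="beta_D"),
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


@dataclass
class SweepPoint:
    """One 1-D sensitivity-sweep result."""

    param_name: str
    value: float
    seed: int
    log2_mean_diff: float
    status: str
    converged: bool


def _cell_seed(seed_policy: str, master: int, i: int, j: int) -> int:
    if seed_policy == "derived":
        return derive_seed(master, i, j)
    if seed_policy == "fixed":
        return int(master)
    raise ValueError(f"unknown seed_policy {seed_policy!r}")


def _run_cell(params: SimulationParams, seed: int) -> tuple[float, str, bool]:
    result = run_pipeline(params, seed)
    report = result.report
    status = report.sentinel or STATUS_OK
    log2 = report.log2_mean_diff
    if not result.trajectory.converged:
        # the diff of the capped state is kept for inspection, but the
        # cell is flagged and rendered as a cross
        status = STATUS_NO_CONVERGENCE
    return log2, status, result.trajectory.converged


def sweep_2d(
    beta_N_values,
    beta_D_values,
    m: float,
    n: float,
    base_params: SimulationParams,
    *,
    seed: int = 0,
    seed_policy: str = "derived",
    done: dict[tuple[int, int], tuple[float, str]] | None = None,
) -> SweepGrid:
    """Run the full pipeline for every (beta_N, beta_D) pair of one panel.

    ``done`` allows resuming: cells present in it (keyed by index pair)
    are copied over instead of recomputed.
    """
    bN = np.asarray(list(beta_N_values), dtype=float)
    bD = np.asarray(list(beta_D_values), dtype=float)
    if bN.size == 0 or bD.size == 0 or np.any(bN <= 0) or np.any(bD <= 0):
        raise ValueError("production-rate axes must be nonempty and positive")
    log2 = np.full((bN.size, bD.size), np.nan)
    status = np.full((bN.size, bD.size), STATUS_OK, dtype=object)
    seeds = np.zeros((bN.size, bD.size), dtype=np.int64)
    for i, beta_N in enumerate(bN):
        for j, beta_D in enumerate(bD):
            seeds[i, j] = _cell_seed(seed_policy, seed, i, j)
            if done is not None and (i, j) in done:
                log2[i, j], status[i, j] = done[(i, j)]
                continue
            params = base_params.with_(beta_N=beta_N, beta_D=beta_D, m=m, n=n)
            log2[i, j], status[i, j], _ = _run_cell(params, int(seeds[i, j]))
    return SweepGrid(bN, bD, float(m), float(n), log2, status, seeds)


def sweep_1d(
    param_name: str,
    values,
    base_params: SimulationParams,
    *,
    seed: int = 0,
    seed_policy: str = "derived",
) -> list[SweepPoint]:
    """Vary one fixed constant over ``values``, one pipeline run per value."""
    if param_name not in SWEEPABLE_1D:
        raise ValueError(
            f"cannot sweep {param_name!r}; choose one of {SWEEPABLE_1D}"
        )
    assert param_name in {f.name for f in fields(SimulationParams)}
    vals = [float(v) for v in values]
    if not vals or any(v <= 0 for v in vals):
        raise ValueError("sweep values must be nonempty and positive")
    out = []
    for k, value in enumerate(vals):
        run_seed = _cell_seed(seed_policy, seed, 0, k)
        params = base_params.with_(**{param_name: value})
        log2, status, converged = _run_cell(params, run_seed)
        out.append(SweepPoint(param_name, value, run_seed, log2, status, converged))
    return out
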