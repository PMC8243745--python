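"""One-call simulate-then-score pipeline shared by sweeps, CLI and scripts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diffstat import DiffReport, compute_diff
from .dynamics import SimulationParams
from .initial import InitSpec, random_initial_state
from .integrate import TrajectoryResult, run_to_equilibrium
from .lattice import LatticeSpec

__all__ = ["PipelineResult", "center_cell", "derive_seed", "run_pipeline"]


def center_cell(lattice: LatticeSpec) -> tuple[int, int]:
    """Default PV placement; on a torus the position is immaterial."""
    return (lattice.height // 2, lattice.width // 2)


def derive_seed(master: int, *key: int) -> int:
    """Deterministic independent sub-seed for a (master, key...) combination."""
    ss = np.random.SeedSequence((int(master),) + tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class PipelineResult:
    seed: int
    trajectory: TrajectoryResult
    report: DiffReport | None  # None when there is no PV cell


def run_pipeline(
    params: SimulationParams,
    seed: int,
    pv_cells: tuple[tuple[int, int], ...] | None = None,
    *,
    engine: str = "compiled",
) -> PipelineResult:
    """Random initial state -> equilibrium -> diff report.

    ``pv_cells=None`` places one PV cell at the lattice center; pass an
    empty tuple for a PV-free run (no diff report is produced then).
    """
    if pv_cells is None:
        pv_cells = (center_cell(params.lattice),)
    spec = InitSpec(seed=seed, mean=params.init_mean, sd=params.init_sd,
                    pv_cells=tuple(pv_cells))
    state = random_initial_state(spec, params)
    traj = run_to_equilibrium(state, params, engine=engine)
    report = compute_diff(traj.final_state, params) if pv_cells else None
    return PipelineResult(seed=seed, trajectory=traj, report=report)
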