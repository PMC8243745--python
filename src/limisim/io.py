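"""Run configuration, result serialization and figure output.

Equilibrium fields are written as plain CSV matrices (a 20x20 field is
tiny and human-diffable), run metadata as JSON, and optional figures as
PNG: grayscale field images with PV cells cross-marked, and log2-diff
heatmaps with crosses on sentinel cells.  A JSON sidecar stores enough to
reconstruct any run or sweep exactly (parameters and seeds included).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .dynamics import SimulationParams
from .lattice import LatticeSpec
from .pipeline import center_cell, run_pipeline
from .sweep import DEFAULT_AXIS, DEFAULT_PANELS, STATUS_OK, SweepGrid, sweep_2d

__all__ = ["RunConfig", "SweepSpec", "run_single", "run_sweep",
           "save_field_csv", "load_field_csv"]

log = logging.getLogger("limisim")


@dataclass(frozen=True)
class SweepSpec:
    """Axes and (m, n) panels of a production-rate sweep."""

    beta_N_values: tuple[float, ...] = tuple(DEFAULT_AXIS)
    beta_D_values: tuple[float, ...] = tuple(DEFAULT_AXIS)
    panels: tuple[tuple[float, float], ...] = DEFAULT_PANELS
    seed_policy: str = "derived"


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run: parameters, seed, placement.

    ``pv_cells=None`` means "one PV cell at the lattice center"; an empty
    tuple runs without any disturbance cell (no diff report then).
    Unspecified fields resolve to the model defaults.
    """

    params: SimulationParams = field(default_factory=SimulationParams)
    seed: int = 0
    pv_cells: tuple[tuple[int, int], ...] | None = None
    outdir: str = "limisim_out"
    images: bool = False
    snapshot_interval: int | None = None  # dump fields every k steps
    sweep: SweepSpec | None = None

    def resolved_pv_cells(self) -> tuple[tuple[int, int], ...]:
        if self.pv_cells is None:
            return (center_cell(self.params.lattice),)
        return tuple(tuple(c) for c in self.pv_cells)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"]["lattice"] = {"width": self.params.lattice.width,
                                  "height": self.params.lattice.height}
        d["pv_cells"] = None if self.pv_cells is None else [list(c) for c in self.pv_cells]
        if self.sweep is not None:
            d["sweep"] = {
                "beta_N_values": list(self.sweep.beta_N_values),
                "beta_D_values": list(self.sweep.beta_D_values),
                "panels": [list(p) for p in self.sweep.panels],
                "seed_policy": self.sweep.seed_policy,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        pd_ = dict(d.get("params", {}))
        if "lattice" in pd_:
            pd_["lattice"] = LatticeSpec(**pd_["lattice"])
        params = SimulationParams(**pd_)
        pv = d.get("pv_cells")
        if pv is not None:
            pv = tuple(tuple(int(x) for x in c) for c in pv)
        sweep = d.get("sweep")
        if sweep is not None:
            sweep = SweepSpec(
                beta_N_values=tuple(sweep["beta_N_values"]),
                beta_D_values=tuple(sweep["beta_D_values"]),
                panels=tuple(tuple(p) for p in sweep["panels"]),
                seed_policy=sweep.get("seed_policy", "derived"),
            )
        snap = d.get("snapshot_interval")
        return cls(params=params, seed=int(d.get("seed", 0)), pv_cells=pv,
                   outdir=d.get("outdir", "limisim_out"),
                   images=bool(d.get("images", False)),
                   snapshot_interval=None if snap is None else int(snap),
                   sweep=sweep)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def save_field_csv(field_: np.ndarray, path) -> None:
    np.savetxt(path, field_, delimiter=",", fmt="%.17g")


def load_field_csv(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def _plot_field(field_: np.ndarray, pv_mask: np.ndarray, title: str, path) -> None:
    """Grayscale panel normalized over non-PV cells; PV cells cross-marked."""
    free = field_[~pv_mask]
    lo, hi = (float(free.min()), float(free.max())) if free.size else (0.0, 1.0)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(field_, cmap="gray", vmin=lo, vmax=hi if hi > lo else lo + 1.0)
    for (r, c) in np.argwhere(pv_mask):
        ax.plot(c, r, "rx", markersize=10, markeredgewidth=2)
    ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def _plot_sweep(grid: SweepGrid, path) -> None:
    """log2-diff heatmap, crosses on sentinel/non-converged cells."""
    fig, ax = plt.subplots(figsize=(5, 4))
    masked = np.ma.masked_invalid(grid.log2)
    im = ax.pcolormesh(np.arange(grid.beta_D_values.size + 1),
                       np.arange(grid.beta_N_values.size + 1),
                       masked, cmap="coolwarm", shading="flat")
    bad = grid.status != STATUS_OK
    for (i, j) in np.argwhere(bad):
        ax.plot(j + 0.5, i + 0.5, "kx", markersize=8, markeredgewidth=2)
    ax.set_xticks(np.arange(grid.beta_D_values.size) + 0.5,
                  [f"{v:g}" for v in grid.beta_D_values], rotation=90)
    ax.set_yticks(np.arange(grid.beta_N_values.size) + 0.5,
                  [f"{v:g}" for v in grid.beta_N_values])
    ax.set_xlabel(r"$\beta_D$")
    ax.set_ylabel(r"$\beta_N$")
    ax.set_title(f"log2(diff), m={grid.m:g}, n={grid.n:g}")
    fig.colorbar(im, ax=ax)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def _run_with_snapshots(config: RunConfig, pv_cells, outdir: Path):
    """Integrate in chunks, dumping the fields every ``snapshot_interval``
    steps under ``snapshots/`` (a debugging aid for slow trajectories)."""
    from .diffstat import compute_diff
    from .initial import InitSpec, random_initial_state
    from .integrate import TrajectoryResult, run_to_equilibrium
    from .pipeline import PipelineResult

    params = config.params
    spec = InitSpec(seed=config.seed, mean=params.init_mean,
                    sd=params.init_sd, pv_cells=tuple(pv_cells))
    state = random_initial_state(spec, params)
    snapdir = outdir / "snapshots"
    snapdir.mkdir(parents=True, exist_ok=True)
    total = 0
    while True:
        chunk = min(config.snapshot_interval, params.max_steps - total)
        part = run_to_equilibrium(state, params, max_steps=chunk)
        state = part.final_state
        total += part.steps
        for name, field_ in (("D", state.D), ("N", state.N), ("R", state.R)):
            save_field_csv(field_, snapdir / f"{name}_{total:09d}.csv")
        if part.converged or total >= params.max_steps:
            break
    traj = TrajectoryResult(state, total, part.final_residual, part.converged)
    report = compute_diff(state, params) if pv_cells else None
    return PipelineResult(seed=config.seed, trajectory=traj, report=report)


def run_single(config: RunConfig) -> dict:
    """Simulate one run and write fields, summary and optional images.

    Returns the summary dict (also written to ``summary.json``); the
    ``converged`` flag tells the caller whether to signal failure.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pv_cells = config.resolved_pv_cells()
    t0 = time.perf_counter()
    if config.snapshot_interval:
        result = _run_with_snapshots(config, pv_cells, outdir)
    else:
        result = run_pipeline(config.params, config.seed, pv_cells)
    elapsed = time.perf_counter() - t0
    traj = result.trajectory
    state = traj.final_state
    for name, field_ in (("D", state.D), ("N", state.N), ("R", state.R)):
        save_field_csv(field_, outdir / f"{name}.csv")
        if config.images:
            _plot_field(field_, state.pv_mask, name, outdir / f"{name}.png")
    summary = {
        "config": config.to_dict(),
        "seed": config.seed,
        "pv_cells": [list(c) for c in pv_cells],
        "steps": traj.steps,
        "model_time": state.t,
        "final_residual": traj.final_residual,
        "converged": traj.converged,
        "elapsed_seconds": elapsed,
        "diff": result.report.to_dict() if result.report is not None else None,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    log.info("run seed=%d: %d steps, residual=%.3g, converged=%s (%.1fs)",
             config.seed, traj.steps, traj.final_residual, traj.converged, elapsed)
    return summary


def _sidecar_path(outdir: Path, m: float, n: float) -> Path:
    return outdir / f"sweep_m{m:g}_n{n:g}.json"


def _load_done(path: Path) -> dict[tuple[int, int], tuple[float, str]]:
    if not path.exists():
        return {}
    with open(path) as fh:
        side = json.load(fh)
    done = {}
    for cell in side.get("cells", []):
        log2 = cell["log2"]
        done[(cell["i"], cell["j"])] = (
            float("nan") if log2 is None else float(log2), cell["status"])
    return done


def run_sweep(config: RunConfig) -> list[SweepGrid]:
    """Run one phase-diagram sweep per (m, n) panel; resumable.

    Each panel writes a CSV grid, a heatmap PNG and a JSON sidecar of
    per-cell records; on rerun, cells already present in the sidecar are
    skipped.
    """
    if config.sweep is None:
        raise ValueError("config has no sweep specification")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grids = []
    for (m, n) in config.sweep.panels:
        side_path = _sidecar_path(outdir, m, n)
        done = _load_done(side_path)
        grid = sweep_2d(
            config.sweep.beta_N_values, config.sweep.beta_D_values, m, n,
            config.params, seed=config.seed,
            seed_policy=config.sweep.seed_policy, done=done or None,
        )
        grid.to_csv(outdir / f"sweep_m{m:g}_n{n:g}.csv")
        _plot_sweep(grid, outdir / f"sweep_m{m:g}_n{n:g}.png")
        cells = [
            {"i": int(i), "j": int(j), "seed": int(grid.seeds[i, j]),
             "log2": None if grid.status[i, j] != STATUS_OK else float(grid.log2[i, j]),
             "status": str(grid.status[i, j])}
            for i in range(grid.log2.shape[0]) for j in range(grid.log2.shape[1])
        ]
        with open(side_path, "w") as fh:
            json.dump({"config": config.to_dict(), "m": m, "n": n,
                       "cells": cells}, fh, indent=2)
        log.info("panel m=%g n=%g done (%d cells)", m, n, len(cells))
        grids.append(grid)
    return grids
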