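"""Explicit Euler time stepping of the LIMI system to its equilibrium.

The update is synchronous: all derivatives are evaluated on the pre-step
snapshot, every cell then moves by ``dt * dX/dt``, negative excursions are
clipped to zero and the PV Delta clamp is reapplied.  The run stops when
the largest derivative magnitude over all three variables of every
non-PV cell falls below ``residual_tol`` (PV cells are excluded from the
convergence check entirely), or when ``max_steps`` is reached, in which
case the result is flagged as non-converged.

Two engines compute the same trajectory: a numba-compiled kernel (the
default — 5e6-step runs at dt=1e-4 need it) and a plain numpy loop built
from the public :func:`limisim.dynamics.rhs`, kept as the readable
reference semantics.  A test asserts they agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .dynamics import GridState, SimulationParams, rhs

__all__ = ["TrajectoryResult", "NumericalBlowupError", "step", "run_to_equilibrium"]


class NumericalBlowupError(RuntimeError):
    """A field became non-finite during integration (unstable step size)."""


@dataclass
class TrajectoryResult:
    """Outcome of a run: final state, step count, residual, convergence flag."""

    final_state: GridState
    steps: int
    final_residual: float
    converged: bool


def step(state: GridState, params: SimulationParams) -> GridState:
    """One synchronous explicit-Euler step (reference implementation).

    Returns a new state; derivative evaluation, clipping and the PV clamp
    are applied in that order and time advances by ``dt``.
    """
    dD, dN, dR = rhs(state, params)
    dt = params.dt
    D = np.maximum(state.D + dt * dD, 0.0)
    N = np.maximum(state.N + dt * dN, 0.0)
    R = np.maximum(state.R + dt * dR, 0.0)
    D[state.pv_mask] = params.pv_delta
    out = GridState(D=D, N=N, R=R, pv_mask=state.pv_mask.copy(), t=state.t + dt)
    _raise_on_blowup(out)
    return out


def _raise_on_blowup(state: GridState) -> None:
    for name, f in (("D", state.D), ("N", state.N), ("R", state.R)):
        bad = ~np.isfinite(f)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise NumericalBlowupError(
                f"non-finite value in field {name} at cell ({r}, {c}) "
                f"after step to t={state.t:g}; reduce dt"
            )


@njit(cache=True, fastmath={"contract", "reassoc", "arcp", "nsz"})
def _kernel(D, N, R, pv, beta_N, beta_D, beta_R, k_t, k_c, gamma, gamma_R,
            k_RS, n, m, pv_delta, dt, tol, max_steps, freeze_pv, resid_scale):
    """Fused derivative/residual/update loop; mutates the fields in place.

    Returns (steps, residual, flag): flag 1 converged, 0 step cap reached,
    -1 non-finite values encountered.  The fastmath subset keeps NaN/inf
    semantics intact (no 'nnan'/'ninf') so the blowup check stays sound.
    """
    H, W = D.shape
    dDf = np.empty((H, W))
    dNf = np.empty((H, W))
    dRf = np.empty((H, W))
    inv_kt = 1.0 / k_t
    inv_kc = 1.0 / k_c
    # integer exponents are the common case; x**float is far slower
    n_int = int(n) if n == math.floor(n) and n <= 8 else 0
    m_int = int(m) if m == math.floor(m) and m <= 8 else 0
    steps = 0
    for it in range(max_steps + 1):
        resid = 0.0
        for i in range(H):
            im1 = i - 1 if i > 0 else H - 1
            ip1 = i + 1 if i < H - 1 else 0
            for j in range(W):
                jm1 = j - 1 if j > 0 else W - 1
                jp1 = j + 1 if j < W - 1 else 0
                D_avg = 0.25 * (((D[im1, j] + D[ip1, j]) + D[i, jm1]) + D[i, jp1])
                N_avg = 0.25 * (((N[im1, j] + N[ip1, j]) + N[i, jm1]) + N[i, jp1])
                cis = N[i, j] * D[i, j] * inv_kc
                dn = beta_N - gamma * N[i, j] - N[i, j] * D_avg * inv_kt - cis
                s = N[i, j] * D_avg
                if n_int > 0:
                    hill = s
                    for _ in range(n_int - 1):
                        hill *= s
                else:
                    hill = s ** n
                dr = beta_R * hill / (k_RS + hill) - gamma_R * R[i, j]
                if m_int > 0:
                    rm = R[i, j]
                    for _ in range(m_int - 1):
                        rm *= R[i, j]
                else:
                    rm = R[i, j] ** m
                dd = (beta_D / (1.0 + rm) - gamma * D[i, j]
                      - D[i, j] * N_avg * inv_kt - cis)
                if pv[i, j]:
                    dd = 0.0
                    if freeze_pv:
                        dn = 0.0
                        dr = 0.0
                else:
                    # `not (x <= resid)` lets NaN poison the residual
                    r = abs(dn)
                    if not (r <= resid):
                        resid = r
                    r = abs(dr)
                    if not (r <= resid):
                        resid = r
                    r = abs(dd)
                    if not (r <= resid):
                        resid = r
                dNf[i, j] = dn
                dRf[i, j] = dr
                dDf[i, j] = dd
        resid *= resid_scale
        if not np.isfinite(resid):
            return steps, resid, -1
        if resid < tol:
            return steps, resid, 1
        if it == max_steps:
            return steps, resid, 0
        for i in range(H):
            for j in range(W):
                v = D[i, j] + dt * dDf[i, j]
                D[i, j] = v if v > 0.0 else 0.0
                v = N[i, j] + dt * dNf[i, j]
                N[i, j] = v if v > 0.0 else 0.0
                v = R[i, j] + dt * dRf[i, j]
                R[i, j] = v if v > 0.0 else 0.0
                if pv[i, j]:
                    D[i, j] = pv_delta
        steps += 1
    return steps, resid, 0  # unreachable


def _residual(state: GridState, params: SimulationParams) -> float:
    """Largest derivative magnitude over all variables of non-PV cells."""
    dD, dN, dR = rhs(state, params)
    free = ~state.pv_mask
    if not free.any():
        return 0.0
    resid = max(
        float(np.max(np.abs(dD[free]))),
        float(np.max(np.abs(dN[free]))),
        float(np.max(np.abs(dR[free]))),
    )
    return resid * params.dt if params.residual_on_increments else resid


def run_to_equilibrium(
    initial: GridState,
    params: SimulationParams,
    *,
    max_steps: int | None = None,
    engine: str = "compiled",
) -> TrajectoryResult:
    """Integrate until the convergence criterion is met or the step cap hits.

    The residual is checked before each update, so the returned state of a
    converged run re-evaluates below ``residual_tol`` (a state already at
    equilibrium returns after zero steps).  Non-convergence sets
    ``converged=False``; the final state is still returned.
    """
    initial.validate(params)
    cap = params.max_steps if max_steps is None else max_steps
    if engine == "compiled":
        state = initial.copy()
        scale = params.dt if params.residual_on_increments else 1.0
        steps, resid, flag = _kernel(
            state.D, state.N, state.R, state.pv_mask,
            params.beta_N, params.beta_D, params.beta_R,
            params.k_t, params.k_c, params.gamma, params.gamma_R,
            params.k_RS, float(params.n), float(params.m),
            params.pv_delta, params.dt, params.residual_tol,
            cap, params.freeze_pv_fields, scale,
        )
        state.t = initial.t + steps * params.dt
        if flag == -1:
            _raise_on_blowup(state)
            raise NumericalBlowupError("non-finite derivatives during integration")
        return TrajectoryResult(state, steps, float(resid), flag == 1)

    if engine != "python":
        raise ValueError(f"unknown engine {engine!r}")
    state = initial.copy()
    steps = 0
    while True:
        resid = _residual(state, params)
        if not np.isfinite(resid):
            raise NumericalBlowupError("non-finite derivatives during integration")
        if resid < params.residual_tol:
            return TrajectoryResult(state, steps, resid, True)
        if steps >= cap:
            return TrajectoryResult(state, steps, resid, False)
        state = step(state, params)
        steps += 1
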