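"""The LIMI (lateral inhibition with mutual inactivation) reaction terms.

Each cell i carries three state variables: Delta ligand D_i, Notch
receptor N_i and a reporter target gene R_i.  Delta and Notch interact in
trans with the four adjacent cells (activating the reporter and mutually
degrading) and in cis within the same cell (mutually inactivating without
signaling).  The reporter represses Delta production — the lateral
inhibition feedback.  The coupled rates are

    dN_i/dt = beta_N - gamma*N_i - N_i*<D>_i/k_t - N_i*D_i/k_c
    dR_i/dt = beta_R*(N_i*<D>_i)^n / (k_RS + (N_i*<D>_i)^n) - gamma_R*R_i
    dD_i/dt = beta_D/(1 + R_i^m) - gamma*D_i - D_i*<N>_i/k_t - N_i*D_i/k_c

where <X>_i is the von Neumann neighbor average.  A portal-vein (PV)
disturbance cell holds its Delta level clamped at a very high constant
(``pv_delta``) irrespective of the Delta rate equation, mimicking the
Jagged1-rich portal vein smooth muscle cells that nucleate bile-duct
differentiation in the embryonic liver.

Note the Hill denominator is ``k_RS + (N*<D>)^n`` with k_RS *not* raised
to n; this follows the source model formulation exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .lattice import LatticeSpec, neighbor_average

__all__ = ["SimulationParams", "GridState", "rhs", "clamp_pv"]


@dataclass(frozen=True)
class SimulationParams:
    """All rate constants, exponents and numerical controls of a run.

    Defaults follow the source model's parameter choice: production and
    degradation rates in arbitrary concentration/time units, a very large
    reporter capacity ``beta_R`` with half-saturation ``k_RS``, strong cis
    inactivation (k_c << k_t) and the portal-vein Delta clamp at 1000 —
    far above any field-cell Delta level.  ``beta_N``/``beta_D`` default
    to the differentiation-permissive case (100 and 10).
    """

    # production rates
    beta_N: float = 100.0
    beta_D: float = 10.0
    beta_R: float = 1_000_000.0
    # interaction constants (inverse = interaction strength)
    k_t: float = 1.0
    k_c: float = 0.1
    # degradation rates (gamma shared by Notch and Delta)
    gamma: float = 1.0
    gamma_R: float = 1.0
    # reporter induction: half-saturation constant and Hill coefficient
    k_RS: float = 300_000.0
    n: float = 3.0
    # lateral-inhibition feedback strength exponent
    m: float = 1.0
    # portal-vein disturbance cell: clamped Delta level
    pv_delta: float = 1000.0
    # numerical controls
    dt: float = 1e-4
    residual_tol: float = 1e-3
    max_steps: int = 5_000_000
    lattice: LatticeSpec = field(default_factory=LatticeSpec)
    # initial-condition distribution and classification cutoff
    init_mean: float = 1.0
    init_sd: float = 0.1
    diff_threshold: float = 2.0
    # model-variant switches (see docs/methods.md)
    freeze_pv_fields: bool = False  # hold PV-cell N and R fixed too, not just D
    residual_on_increments: bool = False  # compare dt*|dX/dt| (not |dX/dt|) to tol

    def __post_init__(self) -> None:
        positive = {
            "k_t": self.k_t, "k_c": self.k_c, "gamma": self.gamma,
            "gamma_R": self.gamma_R, "k_RS": self.k_RS, "pv_delta": self.pv_delta,
            "dt": self.dt, "residual_tol": self.residual_tol,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        # production rates may be zero (e.g. a Delta-free field)
        nonneg = {"beta_N": self.beta_N, "beta_D": self.beta_D,
                  "beta_R": self.beta_R}
        for name, value in nonneg.items():
            if not value >= 0:
                raise ValueError(f"{name} must be nonnegative, got {value}")
        if self.n < 1 or self.m < 1:
            raise ValueError(f"Hill/feedback exponents must be >= 1, got n={self.n}, m={self.m}")
        if self.max_steps < 0:
            raise ValueError("max_steps must be nonnegative")
        if self.init_sd < 0:
            raise ValueError("init_sd must be nonnegative")

    def with_(self, **changes: Any) -> "SimulationParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass
class GridState:
    """Per-cell Delta/Notch/reporter fields plus the PV-cell mask.

    All three fields are nonnegative at all times (the integrator clips
    negative excursions to zero), and every PV cell holds D == pv_delta.
    """

    D: np.ndarray
    N: np.ndarray
    R: np.ndarray
    pv_mask: np.ndarray
    t: float = 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.D.shape

    def copy(self) -> "GridState":
        return GridState(self.D.copy(), self.N.copy(), self.R.copy(),
                         self.pv_mask.copy(), self.t)

    def validate(self, params: SimulationParams | None = None) -> None:
        shapes = {self.D.shape, self.N.shape, self.R.shape, self.pv_mask.shape}
        if len(shapes) != 1:
            raise ValueError(f"field shapes disagree: {shapes}")
        if params is not None and self.shape != params.lattice.shape:
            raise ValueError(
                f"state shape {self.shape} does not match lattice {params.lattice.shape}"
            )
        for name, f in (("D", self.D), ("N", self.N), ("R", self.R)):
            if np.any(f < 0):
                raise ValueError(f"negative values in field {name}")
        if params is not None and not np.all(self.D[self.pv_mask] == params.pv_delta):
            raise ValueError("PV cells must hold D == pv_delta")


def rhs(
    state: GridState, params: SimulationParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time derivatives (dD/dt, dN/dt, dR/dt) of every cell.

    Derivatives are evaluated on the given state snapshot; the Delta
    derivative of PV cells is reported as zero (their Delta is clamped).
    With ``freeze_pv_fields`` the PV cells' Notch and reporter derivatives
    are zeroed as well.
    """
    state.validate(params)
    D, N, R = state.D, state.N, state.R
    lat = params.lattice
    D_avg = neighbor_average(D, lat)
    N_avg = neighbor_average(N, lat)

    cis = N * D / params.k_c
    dN = params.beta_N - params.gamma * N - N * D_avg / params.k_t - cis
    signal = N * D_avg
    hill = signal ** params.n
    dR = params.beta_R * hill / (params.k_RS + hill) - params.gamma_R * R
    dD = (
        params.beta_D / (1.0 + R ** params.m)
        - params.gamma * D
        - D * N_avg / params.k_t
        - cis
    )

    dD = np.where(state.pv_mask, 0.0, dD)
    if params.freeze_pv_fields:
        dN = np.where(state.pv_mask, 0.0, dN)
        dR = np.where(state.pv_mask, 0.0, dR)
    return dD, dN, dR


def clamp_pv(state: GridState, params: SimulationParams) -> GridState:
    """Return a copy of ``state`` with every PV cell's Delta set to ``pv_delta``.

    Idempotent; all other fields are untouched.
    """
    out = state.copy()
    out.D[out.pv_mask] = params.pv_delta
    return out
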