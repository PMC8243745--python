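"""Independent brute-force / closed-form oracles used by the test suite.

Everything here is deliberately written without reusing the package's
vectorized code paths: per-cell Python loops and a scalar root bracketing
of the homogeneous fixed-point system.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from limisim import SimulationParams


def loop_neighbor_average(field: np.ndarray) -> np.ndarray:
    """Per-cell mean over the four toroidal orthogonal neighbors, by loop."""
    h, w = field.shape
    out = np.empty_like(field, dtype=float)
    for i in range(h):
        for j in range(w):
            out[i, j] = (
                field[(i - 1) % h, j] + field[(i + 1) % h, j]
                + field[i, (j - 1) % w] + field[i, (j + 1) % w]
            ) / 4.0
    return out


def loop_diff(R: np.ndarray, pv_cells: list[tuple[int, int]]) -> dict:
    """diff statistic by explicit set construction and per-cell loops."""
    h, w = R.shape
    pv = set(pv_cells)
    neighbors: set[tuple[int, int]] = set()
    for (r, c) in pv:
        for (rr, cc) in [((r - 1) % h, c), ((r + 1) % h, c),
                         (r, (c - 1) % w), (r, (c + 1) % w)]:
            if (rr, cc) not in pv:
                neighbors.add((rr, cc))
    included = [
        (i, j) for i in range(h) for j in range(w)
        if (i, j) not in pv and (i, j) not in neighbors
    ]
    vals = [R[c] for c in included]
    ave = sum(vals) / len(vals)
    sd = (sum((v - ave) ** 2 for v in vals) / len(vals)) ** 0.5
    diffs = {c: (R[c] - ave) / sd for c in sorted(neighbors)} if sd > 0 else None
    return {"ave": ave, "sd": sd, "diffs": diffs,
            "neighbors": sorted(neighbors), "n_included": len(included)}


def homogeneous_fixed_points(params: SimulationParams) -> list[tuple[float, float, float]]:
    """All spatially uniform steady states (D, N, R), by scalar bracketing.

    On the homogeneous manifold the neighbor averages equal the cell's own
    values, so the three rate equations reduce to a single scalar equation
    in D after eliminating N (from the Notch balance) and R (from the
    reporter balance).  Sign changes of that residual over a dense D grid
    are bracketed with Brent's method.
    """
    p = params

    def N_of(D: float) -> float:
        return p.beta_N / (p.gamma + D / p.k_t + D / p.k_c)

    def R_of(D: float) -> float:
        s = N_of(D) * D
        hill = s ** p.n
        return p.beta_R * hill / (p.k_RS + hill) / p.gamma_R

    def g(D: float) -> float:
        N = N_of(D)
        R = R_of(D)
        return (p.beta_D / (1.0 + R ** p.m) - p.gamma * D
                - D * N / p.k_t - N * D / p.k_c)

    if p.beta_D == 0:
        return [(0.0, p.beta_N / p.gamma, 0.0)]
    hi = p.beta_D / p.gamma
    grid = np.concatenate([[1e-12], np.geomspace(1e-9 * hi, hi, 4000)])
    roots = []
    for a, b in zip(grid[:-1], grid[1:]):
        ga, gb = g(a), g(b)
        if ga == 0.0:
            roots.append(a)
        elif ga * gb < 0:
            roots.append(brentq(g, a, b, xtol=1e-14, rtol=1e-14))
    if g(hi) == 0.0:
        roots.append(hi)
    out = []
    for D in roots:
        if not any(abs(D - Dr) <= 1e-9 * max(1.0, Dr) for Dr, _, _ in out):
            out.append((D, N_of(D), R_of(D)))
    return out
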