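# Methods

## Model

`limisim` simulates Delta–Notch signaling on a toroidal 20×20 square
lattice of cells under the *lateral inhibition with mutual inactivation*
(LIMI) scheme.  Each cell *i* carries Delta ligand `D_i`, Notch receptor
`N_i` and a reporter target gene `R_i` (arbitrary concentration units):

    dN_i/dt = β_N − γ N_i − N_i⟨D⟩_i / k_t − N_i D_i / k_c
    dR_i/dt = β_R (N_i⟨D⟩_i)^n / (k_RS + (N_i⟨D⟩_i)^n) − γ_R R_i
    dD_i/dt = β_D / (1 + R_i^m) − γ D_i − D_i⟨N⟩_i / k_t − N_i D_i / k_c

`⟨X⟩_i` is the arithmetic mean over the four von Neumann neighbors
(up/down/left/right with periodic wraparound).  The trans terms
(`X⟨Y⟩/k_t`) couple adjacent cells: productive signaling that consumes
both ligand and receptor and drives the reporter through a Hill function.
The cis term (`N D / k_c`) inactivates ligand and receptor within one
cell without signaling.  The reporter represses Delta production — the
lateral-inhibition feedback — with strength exponent `m`; `n` is the Hill
coefficient of reporter induction.

The Hill denominator is `k_RS + (N⟨D⟩)^n` with `k_RS` *not* raised to
`n`.  That is dimensionally odd but is the source formulation, and all
default constants are calibrated to it; it is implemented verbatim.

A **portal-vein (PV) cell** models the Jagged1-rich portal vein smooth
muscle: its Delta is held at `pv_delta = 1000` — far above any field
value — irrespective of the Delta rate equation.  Its Notch and reporter
still evolve under their own equations by default; the source only
specifies the Delta override, and since the convergence criterion and the
diff statistic both exclude PV cells, the choice is inconsequential
downstream.  `freeze_pv_fields=True` freezes `N` and `R` of PV cells too
for users who prefer the stricter reading.

## Defaults

| parameter | default | meaning |
|---|---|---|
| β_N, β_D | 100, 10 | Notch/Delta production (the differentiation-permissive case; both are swept) |
| β_R | 10⁶ | reporter production capacity |
| k_t, k_c | 1, 0.1 | trans / cis interaction constants (inverse = strength) |
| γ, γ_R | 1, 1 | degradation of Notch & Delta / of reporter |
| k_RS, n | 3·10⁵, 3 | reporter half-saturation and Hill coefficient |
| m | 1 | lateral-inhibition feedback exponent |
| pv_delta | 1000 | PV-cell Delta clamp |
| dt | 10⁻⁴ | Euler step |
| residual_tol | 10⁻³ | convergence threshold on max non-PV derivative |
| max_steps | 5·10⁶ | iteration cap (model time 500 at default dt) |

## Initial conditions

`D(0)` and `N(0)` are independent per-cell draws from Normal(1, 0.1),
clipped at zero (at these moments the clip essentially never fires —
the mean is ten SDs above zero); `R(0) = 0`; then the PV clamp is
applied.  One integer seed feeds one PRNG stream (`numpy` PCG64), so a
seed reproduces a state bit for bit.  The generator covers exactly this
structure — i.i.d. Gaussian noise around a uniform level.  It does not
emulate spatially correlated heterogeneity, cell-size variation,
proliferation or death, so passing tests speak to the model's idealized
lattice, not to liver tissue.

## Integration and convergence

Synchronous explicit Euler: all derivatives are evaluated on the pre-step
snapshot, every cell moves by `dt·dX/dt`, negative excursions are set to
zero, the PV clamp is reapplied.  The run stops when
`max |dX/dt| < residual_tol` over all three variables of every non-PV
cell — the raw derivative, not the `dt`-multiplied increment
(`residual_on_increments=True` switches to the looser increment reading).
The residual is checked before the update, so a converged state
re-evaluates below tolerance.  There is no adaptive stepping; the default
`dt` is the calibrated value and the explicit scheme is stable there
(the stiffest term, cis inactivation inside the PV cell, has rate
`pv_delta/k_c = 10⁴`, exactly marginal at `dt = 10⁻⁴`; the clip bounds
any overshoot and PV cells are excluded from the residual).

Two engines share these semantics: a numba-compiled fused loop (default;
a 5·10⁶-step run takes tens of seconds) and a plain-numpy reference
built from the public `rhs`/`step` functions.  The test suite asserts
their agreement.

At the differentiation condition (β_N=100, β_D=10) roughly one seed in
five does not quite reach the 10⁻³ residual by the iteration cap: a slow
pattern-rearrangement mode leaves the residual near 2–3·10⁻³ at model
time 500.  Such runs are flagged `converged=False`; their diff statistic
is indistinguishable in practice (log2 ≈ 19.2–19.5 either way), so sweep
cells keep the capped-state value alongside a `no-convergence` marker.

## The diff statistic

At equilibrium, `Ave` and `SD` (population SD, dividing by the count) of
the reporter are computed over every cell except the PV cells and their
von Neumann neighbors (395 of 400 cells for a single PV cell).  Each
PV-neighboring cell gets the z-score `diff = (R − Ave)/SD`; a neighbor
with `diff > 2` (strict) is called a cholangiocyte.  The four neighbor
diffs are averaged *before* the log2 transform used in sweep color maps.
A zero SD maps to an `infinity` sentinel, a non-positive average to a
`negative` sentinel; both render as crosses (CSV token `CROSS`).  With
several PV cells the neighbor set is the union of their neighborhoods
minus the PV cells themselves.

## Dispersion contrast of the PV-free conditions

Both PV-free conditions equilibrate into fine-grained two-level patterns
*relative to their own scale*; what separates them is the absolute scale:
SD(R) ≈ 1 and range ≈ 2.5 at β_N=100/β_D=10, versus SD(R) ≈ 1.5·10³ and
range ≈ 3·10³ at β_N=10/β_D=100.  The near-uniform absolute reporter
level of the first condition is what lets a single disturbance cell push
its neighbors hundreds of field-SDs out; the test suite therefore asserts
the contrast on absolute dispersion (SD and range), not on the
coefficient of variation, which is nearly identical between the two
conditions (≈0.96 vs ≈0.86) and does not discriminate them.

## Sensitivity sweeps

`sweep_1d` varies one fixed constant with everything else at base; the
acceptance checks run, per constant, 5 log-spaced values with one seed
per value (a desk-scale setting; the qualitative patterns are
insensitive to the seed, which shifts log2(diff) by ~0.01–0.3).  The
swept ranges are a design choice, since no canonical axes exist for
them:

* β_R and k_RS: ±2 decades — wide enough to expose the reporter-collapse
  regime (very low β_R, or very high k_RS, shrink the reporter scale of
  the whole field until the PV neighbors stand out even in the otherwise
  non-differentiating condition);
* pv_delta: ±1 decade — the clamp dominates everything above ~100, so the
  result is flat;
* k_t, k_c, γ, γ_R: ±a quarter decade — the neighborhood in which these
  constants rescale the pattern without switching its regime.  Outside
  it, strong cis inactivation (k_c ≲ 0.03) or fast degradation (γ ≳ 3)
  reproduce the same reporter-collapse exceedance as low β_R, and a
  tenfold slower clock (γ, γ_R ≈ 0.1) no longer equilibrates within the
  fixed iteration budget.

`dt` is exposed to `sweep_1d` as well but is treated as a numerical
control, not a model parameter, and is not part of the sensitivity
acceptance checks: changing it rescales integration time against the
fixed step cap rather than probing the biology.

## 2-D sweeps

`sweep_2d` maps log2(averaged diff) over a β_N × β_D grid for one (m, n)
panel; the package default is a 10-point log-spaced axis over [1, 10³]
(bracketing both worked cases) and panels (m, n) ∈
{(1,1), (1,3), (2,1), (2,3)} — explicit choices, configurable, since no
canonical values exist beyond the documented m=1, n=3.  Per-cell seeds
derive deterministically from a master seed (`SeedSequence(master, i, j)`),
so grids are reproducible and cells independent; a `fixed` policy reuses
one seed everywhere.  Sweeps resume from their JSON sidecar: completed
cells are not recomputed.

## Numerical choices and degenerate inputs

* Population SD (÷N) in the diff statistic; with 395 included cells the
  sample-SD alternative shifts diff by <0.2%, but one convention is fixed
  for determinism.
* `R^m` uses real-valued powers; `R=0` gives the full Delta production
  β_D exactly.  Integer exponents take a multiply-chain fast path in the
  compiled kernel.
* Lattices must be at least 3×3 so a cell and its neighbors are distinct;
  the diff statistic requires ≥1 PV cell and ≥2 included cells.
* Non-finite fields raise a blowup error naming the first offending
  cell and field rather than converging silently (NaN poisons the
  residual comparison by construction).

## Known limitations

The lattice is square and regular; there is no cell proliferation,
death, or movement, no explicit NICD species, no stochastic (Langevin)
dynamics, and no delayed feedback.  The PV disturbance is a hard clamp
rather than a dynamic boundary.  Conclusions about real periportal
tissue require all of those ingredients; this package reproduces the
idealized disturbance-driven patterning computation only.
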