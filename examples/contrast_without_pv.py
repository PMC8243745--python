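"""Stability toward homogeneity, with and without differentiation.

Runs the two production-rate conditions WITHOUT a portal-vein cell.
At beta_N=100/beta_D=10 the equilibrium reporter field is a fine-grained
pattern with a tiny absolute spread (SD ~ 1); at beta_N=10/beta_D=100 the
field is strongly heterogeneous (SD ~ 1500).  That absolute-dispersion
gap is what lets a disturbance stand out in the first condition and
drown in the second.
"""

import numpy as np

from limisim import SimulationParams, run_pipeline

for label, (bN, bD) in [("high Notch production (beta_N=100, beta_D=10)", (100.0, 10.0)),
                        ("high Delta production (beta_N=10, beta_D=100)", (10.0, 100.0))]:
    params = SimulationParams(beta_N=bN, beta_D=bD, m=1.0, n=3.0)
    result = run_pipeline(params, seed=0, pv_cells=())  # no PV cell
    R = result.trajectory.final_state.R
    print(label)
    print(f"  converged={result.trajectory.converged} after {result.trajectory.steps} steps")
    print(f"  R: mean={R.mean():.4g}  SD={R.std():.4g}  range=[{R.min():.4g}, {R.max():.4g}]")
print()
print("Both fields are patterned relative to their own scale, but the first")
print("is orders of magnitude tighter in absolute terms — a buffered,")
print("nearly homogeneous state.")
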