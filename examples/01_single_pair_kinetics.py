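"""A donor next to an infinitely deep trap: simulation vs closed form.

The smallest nontrivial system — one fluorescent molecule 3 nm from one
trap — has the exact solution P(t) = exp(-(1/tau_total + K(r)) t).  This
script builds the two-molecule generator, propagates the master equation
and prints both curves at a few times.
"""

import numpy as np

from fretquench import (
    MolecularEnsemble,
    PhotophysicalParams,
    build_rate_matrix,
    initial_condition,
    pair_transfer_rate,
    solve_master_equation,
)

params = PhotophysicalParams(dimension=2)  # QY=0.33, tau_total=5 ns, R_F=5 nm
pair = MolecularEnsemble(
    dimension=2,
    box_lengths=[20.0, 20.0],
    positions=[[5.0, 10.0], [8.0, 10.0]],  # 3 nm apart
    orientations=[[1.0, 0.0], [0.0, 1.0]],
    trap_mask=[False, True],
    diameter=1.0,
)

k = pair_transfer_rate(params, 3.0)
print(f"transfer rate at r=3 nm: {k:.4f} ns^-1 (vs 1/tau_fluor = {1/params.tau_fluor:.4f})")

t = np.linspace(0.0, 10.0, 101)
probs = solve_master_equation(build_rate_matrix(pair, params), initial_condition(pair), t)
exact = np.exp(-(1.0 / params.tau_total + k) * t)

print(" t/ns   P_donor(sim)  P_donor(exact)  P_trap(sim)")
for i in (0, 10, 30, 60, 100):
    print(f"{t[i]:5.1f}   {probs[i,0]:12.6f}  {exact[i]:14.6f}  {probs[i,1]:11.6f}")
print("The donor decays faster than its isolated 5 ns lifetime because the")
print("trap drains it at K(3 nm); the trap column only ever gains population.")
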