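"""When does the single-donor analytic law describe the full simulation?

The exact decay of one donor among Poisson-distributed infinitely deep
acceptors is exp(-t/tau_d - Gamma(1-d/6) V_d n (C_DA t)^(d/6)).  A
many-donor simulation approaches it when traps are plentiful (excitation
is caught before migrating) and donors dilute.  This script walks a
three-point path in that direction and prints the relative deviation of
the fitted fixed-b stretched time from tau_theor.
"""

from fretquench import PhotophysicalParams, transfer_microparameter
from fretquench.studies import analytic_convergence_deviations

c_da = transfer_microparameter(PhotophysicalParams())
print(f"C_DA = R_F^6/tau_fluor = {c_da:.2f} nm^6/ns")
for dim in (2, 3):
    print(f"\n{dim}D (fixed b = {dim}/6):")
    print("  n_mol     f_trap   tau_fit      tau_theor    rel.dev")
    for r in analytic_convergence_deviations(dim, n_configs=15, master_seed=11):
        print(
            f"  {r['concentration']:<8g}  {r['trap_fraction']:<6g}  "
            f"{r['tau_fit']:<11.4g}  {r['tau_theor']:<11.4g}  {r['rel_deviation']:.3f}"
        )
print("\nThe deviation shrinks monotonically toward the single-donor limit;")
print("at low trap fractions donor-donor migration breaks the law's assumptions.")
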