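"""Concentration quenching with random traps, and stretched-exponential fits.

Simulates the configuration-averaged fluorescent-population decay of a 2D
ensemble (100x100 nm, 30% random traps) at two molecular concentrations
and fits each curve with the stretched exponential exp(-(t/tau)^b) and the
lifetime-stretched form exp(-t/tau_total - (t/tau)^b).
"""

from fretquench import PhotophysicalParams, fit_decay, simulate_decay

params = PhotophysicalParams(dimension=2)
for conc in (0.01, 0.04):  # nm^-2
    kin = simulate_decay(
        2, 100.0, conc, params,
        trap_model="random", trap_fraction_value=0.3,
        n_configs=25, master_seed=1,
    )
    s = fit_decay(kin, "stretched")
    ls = fit_decay(kin, "lifetime_stretched", fixed_lifetime=params.tau_total)
    print(f"n = {conc} nm^-2 ({int(conc*1e4)} molecules, 30% traps):")
    print(f"  stretched:          tau = {s.tau:8.3f} ns  b = {s.b:.3f}  msd = {s.msd:.2e}")
    print(f"  lifetime-stretched: tau = {ls.tau:8.3f} ns  b = {ls.b:.3f}  msd = {ls.msd:.2e}")

print("Higher concentration quenches harder: tau drops sharply while b stays")
print("well below 1 — the hallmark of dispersive (nonexponential) migration")
print("and trapping kinetics.")
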