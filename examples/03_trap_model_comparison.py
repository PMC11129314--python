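"""Statistical (pair/aggregate) traps vs random traps at equal trap fraction.

Molecules closer than R_trap = 3 nm form quenching clusters.  For a fair
comparison the random model is run at the mean trap fraction the
statistical model actually realized.  Clustered traps leave larger
trap-free regions, so excitation travels further and decays slower.
"""

import numpy as np

from fretquench import ScenarioConfig, compare_trap_models

cfg = ScenarioConfig(
    dimension=2,
    box_lengths_nm=100.0,
    concentrations=[0.005, 0.04],
    traps={"model": "statistical", "r_trap_nm": 3.0},
    n_configs=25,
    master_seed=5,
)
for rec in compare_trap_models(cfg):
    t = rec["statistical"].time_grid
    gap = rec["statistical"].values - rec["random"].values
    i = np.argmax(np.abs(gap))
    print(
        f"n = {rec['concentration']} nm^-2: matched trap fraction "
        f"{rec['matched_trap_fraction']:.3f}, max |stat - rand| = "
        f"{abs(gap[i]):.4f} at t = {t[i]:.1f} ns"
    )
print("At low concentration few clusters form and the two models coincide;")
print("at high concentration the statistical model decays visibly slower.")
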