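"""Effect of dipole orientations on the quenching kinetics.

The same geometries are propagated twice: once with the isotropic-average
rate and once with the kappa^2/<kappa^2> orientation factor per pair.
Unfavourable orientations can shut individual transfer channels (kappa can
vanish at any distance), so orientation-resolved decay is slightly slower.
"""

import numpy as np

from fretquench import ScenarioConfig, compare_orientation

for dim, box, conc in [(2, 100.0, 0.02), (3, 20.0, 0.07)]:
    cfg = ScenarioConfig(
        dimension=dim, box_lengths_nm=box, concentrations=[conc],
        traps={"model": "random", "fractions": [0.3]},
        n_configs=25, master_seed=5,
    )
    rec = compare_orientation(cfg)[0]
    diff = rec["orientation_on"].values - rec["orientation_off"].values
    t = rec["orientation_on"].time_grid
    i = np.argmax(diff)
    print(
        f"{dim}D, n = {conc}: orientation-on minus orientation-off is "
        f"everywhere >= {diff.min():+.4f}, peaking at {diff[i]:+.4f} (t = {t[i]:.1f} ns)"
    )
print("A positive gap means slower decay with orientations included.")
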