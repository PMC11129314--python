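{
  "name": "compare_traps_3d",
  "dimension": 3,
  "box_lengths_nm": 20.0,
  "concentrations": [0.015, 0.07, 0.1],
  "diameter_nm": 1.0,
  "traps": {"model": "statistical", "r_trap_nm": 1.0},
  "photophysics": {"quantum_yield": 0.33, "tau_total_ns": 5.0, "forster_radius_nm": 5.0},
  "n_configs": 100,
  "hard_core": false,
  "master_seed": 0
}
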