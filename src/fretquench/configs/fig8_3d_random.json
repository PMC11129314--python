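{
  "name": "fig8_3d_random",
  "dimension": 3,
  "box_lengths_nm": 20.0,
  "concentrations": [0.01, 0.015, 0.03, 0.07, 0.1],
  "diameter_nm": 1.0,
  "traps": {"model": "random", "fractions": [0.05, 0.1, 0.3, 0.5]},
  "photophysics": {"quantum_yield": 0.33, "tau_total_ns": 5.0, "forster_radius_nm": 5.0},
  "n_configs": 100,
  "fit_models": ["stretched", "lifetime_stretched", "fixed_b"],
  "master_seed": 0
}
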