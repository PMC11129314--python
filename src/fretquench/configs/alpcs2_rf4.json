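{
  "name": "alpcs2_rf4",
  "dimension": 3,
  "box_lengths_nm": 50.0,
  "concentrations": [0.00031, 0.00062, 0.00124, 0.00186, 0.00248, 0.00372, 0.00496, 0.0062, 0.0124],
  "diameter_nm": 1.5,
  "traps": {"model": "statistical", "r_trap_nm": 4.5},
  "photophysics": {"quantum_yield": 0.4, "tau_total_ns": 5.0, "forster_radius_nm": 4.0},
  "n_configs": 100,
  "irf": {"fwhm_ns": 0.1, "center_ns": 3.5},
  "master_seed": 0
}
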