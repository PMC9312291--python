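{
 "seed": 3,
 "n_subjects": 6,
 "atlas_grid": [14, 16, 12],
 "atlas_radius": 1.8,
 "effects": [
  {"region": "LSMA", "condition": "NA", "amplitude": 2.0, "pattern_sd": 0.6},
  {"region": "LSMA", "condition": "NV", "amplitude": 1.4, "pattern_sd": 0.6},
  {"region": "RSMA", "condition": "NA", "amplitude": 1.8, "pattern_sd": 0.5},
  {"region": "RSMA", "condition": "NV", "amplitude": 1.3, "pattern_sd": 0.5},
  {"region": "LIFG", "condition": "NA", "amplitude": 1.6, "pattern_sd": 0.6},
  {"region": "LIFG", "condition": "NV", "amplitude": 1.6, "pattern_sd": 0.6}
 ],
 "noise": {"white_sd": 0.5, "ar1_rho": 0.25, "drift_amplitude": 0.4,
           "n_drift_components": 3, "motion_coupling": 0.05},
 "between_subject_sd": 0.1,
 "smooth_fwhm_mm": 4.0,
 "n_permutations": 200
}
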