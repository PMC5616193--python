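{
  "kind": "cclamp",
  "_note": "INC-like intrinsic cohort; feature means/SDs from the presumed-excitatory (V-) column of the intrinsic-property table; phenotype mixture approximates the reported distributions (ADP-dominant, no LFR)",
  "pattern_probs": {"CON": 0.21, "LAT": 0.21, "LTS": 0.26, "LTS_osc": 0.04, "FIL": 0.19, "LFR": 0.0, "OSC": 0.09},
  "ahp_probs": {"ADP": 0.72, "S+": 0.18, "S-": 0.10},
  "threshold_mean": -45.0, "threshold_sd": 3.0,
  "amplitude_mean": 69.7, "amplitude_sd": 8.4,
  "half_width_mean": 0.39, "half_width_sd": 0.13,
  "ahp_amplitude_mean": 26.4, "ahp_amplitude_sd": 5.5,
  "r_in_mean": 358.0, "r_in_sd": 180.1,
  "c_in_mean": 54.7, "c_in_sd": 23.8,
  "spont_rate_mean": 6.1, "spont_rate_sd": 5.8,
  "isi_cv_mean": 16.3, "isi_cv_sd": 19.5
}
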