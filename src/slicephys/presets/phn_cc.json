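{
  "kind": "cclamp",
  "_note": "PHN-like intrinsic cohort; feature means/SDs from the double-negative (D-) column; includes the cholinergic-associated LFR phenotype",
  "pattern_probs": {"CON": 0.30, "LAT": 0.17, "LTS": 0.12, "LTS_osc": 0.0, "FIL": 0.21, "LFR": 0.10, "OSC": 0.10},
  "ahp_probs": {"ADP": 0.50, "S+": 0.30, "S-": 0.20},
  "threshold_mean": -45.0, "threshold_sd": 3.0,
  "amplitude_mean": 76.9, "amplitude_sd": 8.9,
  "half_width_mean": 0.54, "half_width_sd": 0.14,
  "ahp_amplitude_mean": 29.1, "ahp_amplitude_sd": 5.0,
  "r_in_mean": 572.9, "r_in_sd": 335.3,
  "c_in_mean": 47.6, "c_in_sd": 32.5,
  "spont_rate_mean": 7.1, "spont_rate_sd": 4.3,
  "isi_cv_mean": 8.3, "isi_cv_sd": 13.5
}
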