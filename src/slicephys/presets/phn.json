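{
  "kind": "vclamp_burst",
  "_note": "PHN-like burst-response cohort",
  "baseline_rate_mean": 4.2, "baseline_rate_sd": 2.0,
  "ratio_mean": 9.3, "ratio_sd": 6.5,
  "duration_mean": 2.2, "duration_sd": 0.9,
  "noise_sd": 2.0, "amp_median": 15.0, "amp_sigma_log": 0.4, "amp_min_noise_sd": 4.0,
  "tau_rise_ms": 0.5, "tau_decay_ms": 5.0,
  "n_sweeps": 3, "burst_onset": 3.0, "burst_offset": 3.2,
  "deflection_peak": 30.0, "deflection_return": 0.3, "smoc_rate": 0.0,
  "condition": "control"
}
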