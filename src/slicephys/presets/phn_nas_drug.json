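{
 "kind": "vclamp_burst",
 "_note": "PHN-like NAS arm: duration scaled by the printed mean percent reduction (65.7%), amplitudes by the printed max-EPSC reduction (38.7%); drug-arm duration truth is bias-inverted: the three-adjacent-bin rule carries a ~+0.15 s wait bias at 5 pooled sweeps, so the truth is (ctrl_mean+0.15)*(1-reduction)-0.15 so the expected *measured* reduction equals the printed mean reduction",
 "baseline_rate_mean": 4.2,
 "baseline_rate_sd": 2.0,
 "ratio_mean": 9.3,
 "ratio_sd": 6.5,
 "duration_mean": 0.656,
 "duration_sd": 0.25,
 "noise_sd": 1.5,
 "amp_median": 9.2,
 "amp_sigma_log": 0.4,
 "amp_min_noise_sd": 4.0,
 "tau_rise_ms": 0.5,
 "tau_decay_ms": 5.0,
 "n_sweeps": 5,
 "burst_onset": 3.0,
 "burst_offset": 3.2,
 "deflection_peak": 30.0,
 "deflection_return": 0.3,
 "smoc_rate": 0.0,
 "condition": "drug",
 "drug_name": "NAS"
}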