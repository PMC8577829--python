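{
  "seed": 7,
  "out_dir": "results/demo",
  "n_reference": 10,
  "baseline_ratio": 1.0,
  "group_col": "region",
  "simulation": {
    "seed": 7,
    "n_founders": 60,
    "cycle_time": {"family": "fixed", "mean_hours": 12.0, "cv": 0.0},
    "recombination_time": 0.0,
    "horizon": 50.0,
    "exit_prob": 0.25,
    "partition": {"mode": "deterministic", "pool_size": 10000},
    "detection_delay": 0.0,
    "recombined_fraction": 0.8,
    "founder_pool": 100.0,
    "noise": {
      "multiplicative_cv": 0.0,
      "background_mean": 0.0,
      "background_sd": 0.0
    }
  }
}
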