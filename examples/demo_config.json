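{
  "seed": 1,
  "output_dir": "scratch/demo_run",
  "spectra": {"n_veg": 60, "n_fm": 72, "grid_points": 160},
  "preprocess": {"methods": ["snv", "sg1", "raw"]},
  "pls": {"max_lv": 6},
  "selection": {
    "sfs": {"max_features": 4, "folds": 5},
    "spa": {"max_vars": 4},
    "ipls": {"interval_width": 2, "max_intervals_selected": 4}
  },
  "imaging": {
    "n_scenes": 3,
    "lines": 64,
    "pixels": 96,
    "combinations": [
      [1150, 1400, 1731, 1880, 1920],
      [1150, 1400, 1450, 1731, 1880, 1920]
    ]
  }
}
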