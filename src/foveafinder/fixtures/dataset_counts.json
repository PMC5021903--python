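{
  "comment": "Published dataset bookkeeping for the clinical validation of the fovea detection study: unseen test set composition per device and disease cohort, post-acquisition exclusions, and the printed summary values the arithmetic is checked against.",
  "test_set_total": 240,
  "device_counts": {
    "bRVO": {"spectralis": 42, "cirrus": 33, "topcon": 5},
    "cRVO": {"spectralis": 53, "cirrus": 23, "topcon": 4},
    "nAMD": {"spectralis": 48, "cirrus": 32, "topcon": 0}
  },
  "excluded": {"bRVO": 6, "cRVO": 4, "nAMD": 0},
  "validation_counts": {"bRVO": 74, "cRVO": 76, "nAMD": 80},
  "printed": {
    "accuracy_pct": {"bRVO": 84, "cRVO": 89, "nAMD": 88},
    "mean_abs_distance_um": 195.5,
    "cme_weighted_mean_um": 162.3,
    "spectralis_count": 143,
    "validation_total": 230
  }
}
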