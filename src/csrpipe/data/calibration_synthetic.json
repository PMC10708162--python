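{
  "version": "synthetic-1.0",
  "comment": "Default calibration matched to the csrpipe synthetic trait generator's ranges. For real floras substitute bounds calibrated on a global reference species set.",
  "axes": {
    "C": {
      "trait": "LA",
      "transform": "sqrt_of_proportion_of_max",
      "params": {"max_value": 50000.0},
      "calib_min": 0.0,
      "calib_max": 0.35
    },
    "S": {
      "trait": "LDMC",
      "transform": "logit_of_percent",
      "params": {},
      "calib_min": -2.1972245773362196,
      "calib_max": 0.8472978603872036
    },
    "R": {
      "trait": "SLA",
      "transform": "natural_log",
      "params": {},
      "calib_min": 2.302585092994046,
      "calib_max": 4.0
    }
  }
}
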