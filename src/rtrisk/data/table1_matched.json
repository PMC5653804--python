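{
  "description": "Propensity-matched baseline characteristics of the 32:32 IMRT/VMAT breast radiotherapy cohort: per-arm category counts. Ages are reported as bin counts plus the arm mean and range.",
  "arms": {
    "IMRT": {
      "n": 32,
      "age_mean": 53,
      "age_range": [28, 70],
      "age_bins": {"<=40": 3, "41-50": 8, "51-60": 14, ">61": 7},
      "scf": {"no": 13, "yes": 19},
      "ajcc": {"1": 16, "2": 5, "3": 11},
      "t_stage": {"1": 12, "2": 18, "3": 2, "4": 0},
      "n_stage": {"0": 14, "1": 8, "2": 4, "3": 6},
      "chemo": {"no": 10, "yes": 22},
      "rp_grade": {"0": 14, "1": 10, "2": 7, "3": 1}
    },
    "VMAT": {
      "n": 32,
      "age_mean": 51,
      "age_range": [33, 74],
      "age_bins": {"<=40": 4, "41-50": 9, "51-60": 12, ">61": 7},
      "scf": {"no": 21, "yes": 11},
      "ajcc": {"1": 16, "2": 5, "3": 11},
      "t_stage": {"1": 15, "2": 14, "3": 2, "4": 1},
      "n_stage": {"0": 17, "1": 6, "2": 5, "3": 4},
      "chemo": {"no": 16, "yes": 16},
      "rp_grade": {"0": 19, "1": 10, "2": 2, "3": 1}
    }
  }
}
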