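{
  "dataset": "rodent",
  "species": "Clethrionomys glareolus",
  "units": {
    "k1": "per uGy",
    "c3": "per year",
    "k_bac": "per year",
    "k_TE": "per uGy",
    "k_NTE": "per year",
    "kappa": "per year"
  },
  "params": {
    "k1": 0.323,
    "c3": 4.54e-05,
    "k_bac": 1.07e-06,
    "k_TE": 3.17e-09,
    "k_NTE": 0.025,
    "kappa": 4.80e-05
  },
  "ci95": {
    "k1": [0.187, 0.625],
    "c3": [2.61e-05, 8.05e-05],
    "k_bac": [2.79e-07, 1.86e-06],
    "k_TE": ["<1e-9", 4.36e-04],
    "k_NTE": [0.021, 0.030],
    "kappa": [4.68e-05, 4.45e-04]
  }
}
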