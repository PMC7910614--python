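{
  "dataset": "plant",
  "species": "Arabidopsis thaliana",
  "units": {
    "k1": "per uGy",
    "c3": "per year",
    "k_bac": "per year",
    "k_TE": "per uGy",
    "k_NTE": "per year",
    "kappa": "per year"
  },
  "params": {
    "k1": 3.105,
    "c3": 12.983,
    "k_bac": 0.044,
    "k_TE": 2.15e-06,
    "k_NTE": 0.057,
    "kappa": 0.515
  },
  "ci95": {
    "k1": [0.026, ">1e2"],
    "c3": [0.003, ">1e2"],
    "k_bac": [0.021, 0.067],
    "k_TE": [4.95e-07, 1.31e-05],
    "k_NTE": [0.023, 0.094],
    "kappa": [0.166, 1.228]
  }
}
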