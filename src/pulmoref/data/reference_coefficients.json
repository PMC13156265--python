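{
  "raw": {
    "units": "cmH2O.s/l",
    "mu_transform": "log",
    "mu": {
      "intercept": 5.36400,
      "sqrt_mass": -0.07261,
      "strain_wistar": -0.07227,
      "sex_male": 0.24217,
      "peep": {"0": 0.00000, "1": -0.20376, "2": -0.36403, "3": -0.51259, "4": -0.65403, "6": -0.96527}
    },
    "sigma": {
      "intercept": -1.17594,
      "strain_wistar": -0.12428,
      "peep": {"0": 0.00000, "1": -0.19736, "2": -0.21221, "3": -0.16229, "4": -0.05226, "6": 0.06301}
    }
  },
  "g": {
    "units": "cmH2O/l",
    "mu_transform": "log",
    "mu": {
      "intercept": 7.87594,
      "sqrt_mass": -0.06022,
      "strain_wistar": -0.05717,
      "sex_male": 0.16888,
      "peep": {"0": 0.00000, "1": -0.17255, "2": -0.27962, "3": -0.36856, "4": -0.45209, "6": -0.53716}
    },
    "sigma": {
      "intercept": -1.85751,
      "sex_male": 0.12800,
      "peep": {"0": 0.00000, "1": -0.25486, "2": -0.29300, "3": -0.23964, "4": -0.26472, "6": -0.32089}
    }
  },
  "h": {
    "units": "cmH2O/l",
    "mu_transform": "log",
    "mu": {
      "intercept": 9.98623,
      "sqrt_mass": -0.09948,
      "strain_wistar": -0.05654,
      "sex_male": 0.20138,
      "peep": {"0": 0.00000, "1": -0.20777, "2": -0.39299, "3": -0.58629, "4": -0.76092, "6": -0.98447}
    },
    "sigma": {
      "intercept": -1.89371,
      "mass": 0.00078,
      "sex_male": -0.07682
    }
  },
  "eelv": {
    "units": "ml",
    "mu_transform": "identity",
    "mu": {
      "intercept": -5.29284,
      "sqrt_mass": 0.58809,
      "strain_wistar": -0.16721,
      "sex_male": -0.27947,
      "peep": {"0": 0.00000, "1": 0.82506, "2": 1.57536, "3": 2.47960, "4": 3.46782, "6": 5.32320}
    },
    "sigma": {
      "intercept": -0.87845,
      "mass": 0.00413,
      "strain_wistar": -0.13945,
      "sex_male": -0.41105,
      "peep": {"0": 0.00000, "1": 0.02265, "2": 0.13399, "3": 0.27625, "4": 0.45725, "6": 0.70147}
    }
  }
}
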