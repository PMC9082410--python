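{
  "config": {
    "beta": {
      "age_sq": -0.00022,
      "annual_income_group": 0.006,
      "consumption": 0.3,
      "education_years": 0.003,
      "gender": 0.0,
      "health_status": 0.008,
      "insurance": 0.02,
      "married": 0.005,
      "monthly_income_group": 0.0,
      "residence_rural": -0.02
    },
    "city_effect_sd": 0.05,
    "community_effect_sd": 0.05,
    "consumption_beta_income_scale": null,
    "consumption_loading": 0.765,
    "covariate_specs": {
      "age": {
        "high": 80.0,
        "kind": "truncnorm",
        "low": 18.0,
        "mean": 35.0,
        "sd": 11.3
      },
      "annual_income_group": {
        "kind": "quantile",
        "n_groups": 6
      },
      "education_years": {
        "kind": "categorical",
        "probs": [
          0.075,
          0.22,
          0.28,
          0.23,
          0.14,
          0.055
        ],
        "values": [
          0,
          6,
          9,
          12,
          16,
          19
        ]
      },
      "gender": {
        "kind": "bernoulli",
        "p": 0.51
      },
      "health_status": {
        "kind": "categorical",
        "probs": [
          0.05,
          0.15,
          0.35,
          0.3,
          0.15
        ],
        "values": [
          1,
          2,
          3,
          4,
          5
        ]
      },
      "insurance": {
        "kind": "bernoulli",
        "p": 0.37
      },
      "married": {
        "kind": "bernoulli",
        "p": 0.59
      },
      "monthly_income_group": {
        "kind": "quantile",
        "n_groups": 4
      },
      "residence_rural": {
        "kind": "bernoulli",
        "p": 0.44
      }
    },
    "discretize": true,
    "intercept": 2.53,
    "likert_levels": 5,
    "mc_n": 2000000,
    "n_cities": 5,
    "n_communities": 15,
    "n_consumption_items": 5,
    "n_respondents": 50,
    "noise_sd": 0.6,
    "outcome_scale": "log",
    "rank_corr": {
      "age": 0.25,
      "annual_income_group": 0.4,
      "education_years": 0.3,
      "gender": 0.03,
      "health_status": 0.2,
      "insurance": 0.15,
      "married": 0.1,
      "monthly_income_group": 0.4,
      "residence_rural": -0.25
    },
    "seed": 42,
    "weight_scheme": "uniform"
  },
  "truth": {
    "beta": {
      "age_sq": -0.00022,
      "annual_income_group": 0.006,
      "consumption": 0.3,
      "education_years": 0.003,
      "gender": 0.0,
      "health_status": 0.008,
      "insurance": 0.02,
      "married": 0.005,
      "monthly_income_group": 0.0,
      "residence_rural": -0.02
    },
    "intercept": 2.53,
    "n_respondents": 50,
    "noise_sd": 0.6,
    "outcome_scale": "log",
    "seed": 42
  }
}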