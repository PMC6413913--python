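{
  "outcome": "mp_w",
  "intercept": 476.8,
  "terms": [
    {"feature": "max VE", "coef": 105.5},
    {"feature": "slope 1st min of VO2 vs. time", "coef": 36.4},
    {"feature": "max VO2", "coef": -33.8},
    {"feature": "max slope * max speed", "coef": 27.6}
  ],
  "scaler": null,
  "provenance": {
    "source": "reference mean-power prediction equation (re-encoded, standardized features)",
    "reported_validation": {"spearman_r": 0.9, "spearman_sd": 0.07, "rmse_w": 73, "pct_err_mean": 16, "pct_err_sd": 14}
  }
}
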