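{
  "outcome": "pp_w",
  "intercept": 638.4,
  "terms": [
    {"feature": "max VE", "coef": 170.3},
    {"feature": "max RF", "coef": -43.5},
    {"feature": "max VO2", "coef": -77.5},
    {"feature": "max slope * max speed", "coef": 98.6},
    {"feature": "slope VCO2 versus VE", "coef": 39.3},
    {"feature": "VO2max/(max slope * max speed)", "coef": 53.0}
  ],
  "scaler": null,
  "provenance": {
    "source": "reference peak-power prediction equation (re-encoded, standardized features)",
    "reported_validation": {"spearman_r": 0.94, "spearman_sd": 0.1, "rmse_w": 96, "pct_err_mean": 19, "pct_err_sd": 18}
  }
}
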