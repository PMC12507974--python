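{
 "metrics_columns": ["subject", "stim", "condition", "trial", "mean_rs", "mean_rs_low", "mean_rs_high", "alpha", "excluded"],
 "coefficient_columns": ["term", "estimate", "se", "t", "p"],
 "contrast_columns": ["contrast", "estimate", "se", "df", "t_ratio", "p_value"],
 "sway_coefficient_terms": ["Intercept", "LDLPFC", "RDLPFC", "Easy", "Hard"],
 "error_coefficient_terms": ["Intercept", "LDLPFC", "RDLPFC", "Hard"],
 "report_files": [
  "coefficients_mean_rs.csv", "contrasts_mean_rs.csv",
  "coefficients_mean_rs_low.csv", "contrasts_mean_rs_low.csv",
  "coefficients_mean_rs_high.csv", "contrasts_mean_rs_high.csv",
  "coefficients_alpha.csv", "contrasts_alpha.csv",
  "coefficients_abs_error.csv",
  "metrics.csv", "run_log.json"
 ]
}
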