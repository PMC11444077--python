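# Published US inputs for the attributable preterm-birth calculation.
#
# Percentile profiles: weighted 10th/25th/50th/75th/90th percentiles of
# log10 uM molar-sum urinary exposure in 16-49-year-old women, NHANES
# 2017-18 (complex-survey weighted). Per-bin risk ratios come from pooled
# US pregnancy-cohort logistic fits of preterm birth on the corresponding
# exposure bins. Continuous-path slopes are weeks of gestational age lost
# per log10-unit exposure increase.
#
# Birth statistics: NVSS natality, 2018. The per-case preterm-birth cost is
# a 2016 literature estimate CPI-adjusted (Medical Care CPI) to 2018; both
# published per-case values are carried because the source reports use both.

percentiles:               # [p10, p25, p50, p75, p90], log10 uM
  DEHP: [-1.773, -1.597, -1.278, -1.055, -0.834]
  DiNP: [-2.239, -2.044, -1.768, -1.533, -1.195]
  DiDP: [-3.054, -2.753, -2.452, -2.209, -1.941]

continuous_slope:          # weeks lost per log10 unit
  DEHP: 0.15
  DiNP: 0.461
  DiDP: 0.279

per_bin_rr:                # risk ratio per bin [p25, p50, p75, p90]
  DEHP: [1.07, 1.22, 1.24, 1.45]
  DiNP: [1.15, 1.42, 1.46, 2.16]
  DiDP: [1.14, 1.31, 1.27, 1.64]

per_log10_or:              # pooled-cohort OR for preterm per log10 unit
  DEHP: 1.45
  DiNP: 2.25
  DiDP: 1.69

ga_mean_weeks: 38.73
ga_sd_weeks: 2.82
preterm_threshold_weeks: 37.0
total_births: 3664651
singleton_preterm_births: 242019
baseline_preterm_rate: 0.1002
per_case_cost_2018_usd: 67836    # CPI-adjusted from the 2016 estimate
per_case_cost_alt_usd: 67665     # alternative published 2018 value
per_case_cost_2016_usd: 64815
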