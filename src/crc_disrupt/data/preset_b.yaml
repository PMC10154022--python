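# Natural-history preset B: gamma frailty, slower growth, longer preclinical
# sojourn, lesion-based FIT positivity.
label: preset-B
adenoma_onset:
  age_breaks: [0, 30, 40, 50, 60, 70]
  rates: [0.0, 0.002, 0.006, 0.011, 0.018, 0.024]
  frailty:
    distribution: gamma
    variance: 1.3
growth:
  rate_median_mm_per_year: 0.45
  rate_sigma_log: 0.7
  initial_diameter_mm: 1.0
  medium_threshold_mm: 6.0
  large_threshold_mm: 10.0
  reach_probability: 1.0
transformation:
  annual_prob_small: 0.00025
  annual_prob_medium: 0.0015
  annual_prob_large: 0.033
sojourn:
  distribution: lognormal
  mean_years: 5.0
  sd_years: 2.5
crc_survival:
  clinically_detected:
    cure_probability: 0.38
    exp_mean_years: 4.0
  screen_detected:
    cure_probability: 0.68
    exp_mean_years: 6.5
fit:
  positivity_mode: per_lesion
  profile: miscan
incidence_target_band: [0.04, 0.07]
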