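# Natural-history preset A: lognormal person-level frailty, faster growth,
# shorter preclinical sojourn, person-based FIT positivity.
label: preset-A
adenoma_onset:
  age_breaks: [0, 30, 40, 50, 60, 70]
  rates: [0.0, 0.0015, 0.007, 0.012, 0.016, 0.020]
  frailty:
    distribution: lognormal
    variance: 1.0
growth:
  rate_median_mm_per_year: 0.55
  rate_sigma_log: 0.6
  initial_diameter_mm: 1.0
  medium_threshold_mm: 6.0
  large_threshold_mm: 10.0
  reach_probability: 1.0
transformation:
  annual_prob_small: 0.0003
  annual_prob_medium: 0.0018
  annual_prob_large: 0.026
sojourn:
  distribution: lognormal
  mean_years: 3.5
  sd_years: 2.0
crc_survival:
  clinically_detected:
    cure_probability: 0.40
    exp_mean_years: 4.5
  screen_detected:
    cure_probability: 0.72
    exp_mean_years: 6.0
fit:
  positivity_mode: per_person
  profile: crcspin
incidence_target_band: [0.04, 0.07]
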