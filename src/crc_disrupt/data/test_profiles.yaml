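# Per-lesion test sensitivity and specificity by modality.
# Colonoscopy specificity (detection of non-adenomatous lesions) is carried
# for completeness but not used in simulation: it only matters for burden
# outcomes, which are out of scope.
colonoscopy:
  high:
    sens_small: 0.75
    sens_medium: 0.85
    sens_large: 0.95
    sens_preclinical: 0.95
    specificity: 0.86
  low:
    sens_small: 0.55
    sens_medium: 0.70
    sens_large: 0.90
    sens_preclinical: 0.95
    specificity: 0.86
fit:
  # positive-with-the-most-advanced-lesion convention
  crcspin:
    sens_small: 0.05
    sens_medium: 0.15
    sens_large: 0.22
    sens_preclinical: 0.74
    specificity: 0.97
    positivity_mode: per_person
  # lesion-based convention; preclinical sensitivity split into early/late
  # halves of the sojourn
  miscan:
    sens_small: 0.00
    sens_medium: 0.114
    sens_large: 0.159
    sens_preclinical_early: 0.62565
    sens_preclinical_late: 0.886
    specificity: 0.97
    positivity_mode: per_lesion
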