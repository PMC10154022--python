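second_category,first_category,interval_years
no_prior,adenoma_1_2_small,7
no_prior,adenoma_3_4_small,3
no_prior,adenoma_5_10_small_or_any_large,3
no_prior,adenoma_gt10,1
normal,normal,10
normal,adenoma_1_2_small,7
normal,adenoma_3_4_small,3
normal,adenoma_5_10_small_or_any_large,3
normal,adenoma_gt10,1
adenoma_1_2_small,normal,10
adenoma_1_2_small,adenoma_1_2_small,7
adenoma_1_2_small,adenoma_3_4_small,3
adenoma_1_2_small,adenoma_5_10_small_or_any_large,3
adenoma_1_2_small,adenoma_gt10,1
adenoma_3_4_small,normal,10
adenoma_3_4_small,adenoma_1_2_small,7
adenoma_3_4_small,adenoma_3_4_small,3
adenoma_3_4_small,adenoma_5_10_small_or_any_large,3
adenoma_3_4_small,adenoma_gt10,1
adenoma_5_10_small_or_any_large,normal,5
adenoma_5_10_small_or_any_large,adenoma_1_2_small,5
adenoma_5_10_small_or_any_large,adenoma_3_4_small,3
adenoma_5_10_small_or_any_large,adenoma_5_10_small_or_any_large,3
adenoma_5_10_small_or_any_large,adenoma_gt10,1
adenoma_gt10,normal,5
adenoma_gt10,adenoma_1_2_small,5
adenoma_gt10,adenoma_3_4_small,3
adenoma_gt10,adenoma_5_10_small_or_any_large,3
adenoma_gt10,adenoma_gt10,1
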