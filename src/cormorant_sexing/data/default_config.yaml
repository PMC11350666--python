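# Default simulation parameters for a great-cormorant morphometric sample.
#
# Sex-specific means (mm) and coefficients of variation are the published
# descriptive statistics for the northern-Poland population; between-measurement
# correlation is not published and defaults to a uniform 0.5, plausible for
# skeletal size traits. Missingness rates reproduce the unequal per-measurement
# sample sizes of the source dataset (wing measured on every bird, tarsus on
# roughly half).
sex_means:
  M:
    wing_length: 352.8
    bill_length: 70.60
    max_bill_depth: 14.51
    min_bill_depth: 13.26
    tarsus_length: 69.19
  F:
    wing_length: 332.2
    bill_length: 63.53
    max_bill_depth: 12.91
    min_bill_depth: 11.70
    tarsus_length: 64.73
cvs:
  M:
    wing_length: 0.021
    bill_length: 0.044
    max_bill_depth: 0.055
    min_bill_depth: 0.049
    tarsus_length: 0.038
  F:
    wing_length: 0.027
    bill_length: 0.052
    max_bill_depth: 0.069
    min_bill_depth: 0.052
    tarsus_length: 0.038
# Additive mean shift applied to adults (mm); zero mirrors the finding that
# ages share one distribution within a sex.
adult_offset:
  wing_length: 0.0
  bill_length: 0.0
  max_bill_depth: 0.0
  min_bill_depth: 0.0
  tarsus_length: 0.0
# Uniform pairwise correlation between measurements within a bird.
correlation: 0.5
# Birds per sex x age class; totals per sex (218 M, 139 F) match the published
# wing-length sample sizes, split by the study's overall juvenile:adult ratio.
group_sizes:
  M: {juv: 128, ad: 90}
  F: {juv: 81, ad: 58}
# Per-measurement probability that a cell is missing (MCAR); chosen so the
# expected non-missing counts match the published per-measurement sample sizes.
missingness:
  wing_length: 0.0
  bill_length: 0.168
  max_bill_depth: 0.162
  min_bill_depth: 0.339
  tarsus_length: 0.493
seed: 20240901
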