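# Default cohort-generator calibration: marginal prevalences of the
# published AYR 3.0 user population (N=143,657).  Family-history flag
# prevalences are conditional on knowing one's family history; gene
# positivity probabilities are conditional on a personal testing history.
n: 1000
seed: 0

age_bin_weights:
  "18-29": 0.5882
  "30-39": 0.2256
  "40-49": 0.1215
  "50-64": 0.0567
  "≥65": 0.0080

race_ethnicity_weights:
  white: 0.6768
  african_american: 0.0348
  asian: 0.0311
  other_or_multiple: 0.1561
  ashkenazi_jewish: 0.0050
  hispanic_latina: 0.0962

p_breast_cancer_only: 0.0320
p_ovarian_cancer_only: 0.0089
p_breast_and_ovarian: 0.0082

p_personal_tested: 0.0368
p_high_gene_given_tested: 0.25
p_moderate_gene_given_tested: 0.05
p_family_member_tested: 0.2413
p_family_positive_given_tested: 0.30

p_family_history_known: 0.8668
fh_prevalences:
  fh_early_onset_breast: 0.1815
  fh_triple_negative: 0.0407
  fh_multiple_breast_same_relative: 0.1145
  fh_multiple_breast_one_le50: 0.0955
  fh_male_breast: 0.0070
  fh_ovarian: 0.1163
  fh_metastatic_prostate: 0.0544
  fh_pancreatic: 0.0817
  fh_three_or_more_cancers_one_side: 0.05

p_chest_radiation: 0.0107
p_abnormal_biopsy: 0.0245
p_pcos: 0.0962
p_dense_breasts: 0.1695

p_alcohol_ge2_per_day: 0.1126
p_exercise_lt150_min: 0.6054
p_current_smoker: 0.1518
p_ever_pregnant: 0.415
p_breastfed_given_pregnant: 0.415
bmi_mean: 28.22
bmi_sd: 7.63
bmi_min: 12.0

# Optional dependence hook; list of [factor_a, factor_b, odds_ratio].
pairwise_odds_ratios: []
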