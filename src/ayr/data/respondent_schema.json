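{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "AYR cohort CSV row",
  "description": "One quiz completion. Booleans are encoded 0/1; personal_positive_genes is a semicolon-joined list of gene symbols ('' = none); breastfed may be empty (missing). Column order in the CSV follows the property order below.",
  "type": "object",
  "properties": {
    "id": {"type": "string"},
    "age": {"type": "integer", "minimum": 18},
    "race": {"enum": ["white", "african_american", "asian", "other_or_multiple"]},
    "ashkenazi_jewish": {"enum": [0, 1]},
    "hispanic_latina": {"enum": [0, 1]},
    "personal_breast_cancer": {"enum": [0, 1]},
    "personal_ovarian_cancer": {"enum": [0, 1]},
    "personal_tested": {"enum": [0, 1]},
    "personal_positive_genes": {
      "type": "string",
      "pattern": "^((BRCA1|BRCA2|MSH2|MLH1|EPCAM|STK11|BRIP1|RAD51C|RAD51D|PMS2|MSH6)(;(BRCA1|BRCA2|MSH2|MLH1|EPCAM|STK11|BRIP1|RAD51C|RAD51D|PMS2|MSH6))*)?$"
    },
    "family_member_tested": {"enum": [0, 1]},
    "family_member_positive": {"enum": [0, 1]},
    "family_history_known": {"enum": [0, 1]},
    "fh_early_onset_breast": {"enum": [0, 1]},
    "fh_triple_negative": {"enum": [0, 1]},
    "fh_multiple_breast_same_relative": {"enum": [0, 1]},
    "fh_multiple_breast_one_le50": {"enum": [0, 1]},
    "fh_male_breast": {"enum": [0, 1]},
    "fh_ovarian": {"enum": [0, 1]},
    "fh_metastatic_prostate": {"enum": [0, 1]},
    "fh_pancreatic": {"enum": [0, 1]},
    "fh_three_or_more_cancers_one_side": {"enum": [0, 1]},
    "chest_radiation": {"enum": [0, 1]},
    "abnormal_biopsy": {"enum": [0, 1]},
    "pcos": {"enum": [0, 1]},
    "dense_breasts": {"enum": [0, 1]},
    "bmi": {"type": "number", "exclusiveMinimum": 0},
    "alcohol_ge2_per_day": {"enum": [0, 1]},
    "exercise_lt150_min": {"enum": [0, 1]},
    "current_smoker": {"enum": [0, 1]},
    "breastfed": {"enum": [0, 1, ""]}
  },
  "required": [
    "id", "age", "race", "ashkenazi_jewish", "hispanic_latina",
    "personal_breast_cancer", "personal_ovarian_cancer", "personal_tested",
    "personal_positive_genes", "family_member_tested", "family_member_positive",
    "family_history_known", "fh_early_onset_breast", "fh_triple_negative",
    "fh_multiple_breast_same_relative", "fh_multiple_breast_one_le50",
    "fh_male_breast", "fh_ovarian", "fh_metastatic_prostate", "fh_pancreatic",
    "fh_three_or_more_cancers_one_side", "chest_radiation", "abnormal_biopsy",
    "pcos", "dense_breasts", "bmi", "alcohol_ge2_per_day", "exercise_lt150_min",
    "current_smoker", "breastfed"
  ],
  "allOf": [
    {
      "description": "positive genes imply personal testing",
      "if": {"properties": {"personal_positive_genes": {"pattern": "^$"}}},
      "then": {},
      "else": {"properties": {"personal_tested": {"const": 1}}}
    },
    {
      "description": "positive family member implies family testing",
      "if": {"properties": {"family_member_positive": {"const": 1}}},
      "then": {"properties": {"family_member_tested": {"const": 1}}}
    },
    {
      "description": "unknown family history forces all fh_* flags to 0",
      "if": {"properties": {"family_history_known": {"const": 0}}},
      "then": {
        "properties": {
          "fh_early_onset_breast": {"const": 0},
          "fh_triple_negative": {"const": 0},
          "fh_multiple_breast_same_relative": {"const": 0},
          "fh_multiple_breast_one_le50": {"const": 0},
          "fh_male_breast": {"const": 0},
          "fh_ovarian": {"const": 0},
          "fh_metastatic_prostate": {"const": 0},
          "fh_pancreatic": {"const": 0},
          "fh_three_or_more_cancers_one_side": {"const": 0}
        }
      }
    }
  ]
}
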