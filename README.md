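# ayr-triage

Rule-based triage of breast and ovarian cancer risk, for biostatisticians
and tool builders who need a tested, scriptable implementation of the
*Assess Your Risk* (AYR) questionnaire algorithm together with the
machinery to validate it against NCCN genetic-testing eligibility criteria.

Hereditary breast/ovarian cancer screening has a recognition problem:
current clinical practice identifies only a small fraction of asymptomatic
carriers of susceptibility variants. Population-facing questionnaires like
the AYR try to close that gap by triaging every respondent into
**average**, **increased** or **high** risk from 26 yes/no-style questions
— family history, genetic-testing results, and a few factors borrowed from
the Gail and Tyrer-Cuzick questionnaires. This package implements:

- **the AYR rule engine** (`ayr.classifier`) — per-site (breast, ovarian)
  categories with the list of fired rules:
  - *high* ⇔ a personal positive test on the high-penetrance panel
    {BRCA1, BRCA2, MSH2, MLH1, EPCAM, STK11};
  - *increased* ⇔ a personal positive on the moderate/lower panel
    {BRIP1, RAD51C, RAD51D, PMS2, MSH6}, a positive relative with no
    personal testing history, any family-history flag, or the extra
    factors — chest radiation / abnormal biopsy (breast), PCOS (ovarian);
  - *average* otherwise. Health behaviors and dense breasts never change a
    category.
- **an independently constructed NCCN reference classifier**
  (`ayr.reference`) — binary eligible/not-eligible from the quiz-reduced
  NCCN criteria, plus an augmented variant that adds the three AYR-only
  factors.
- **the concordance analysis** (`ayr.concordance`) — exclusion filtering,
  2×2 confusion matrices with the NCCN label as gold standard, sensitivity
  = TP/(TP+FN), specificity = TN/(TN+FP), PPV, NPV, and the uncorrected
  McNemar test χ² = (b−c)²/(b+c) on the discordant cells, overall or
  stratified by race/ethnicity (6 strata) or age group (5 bins).
- **synthetic cohort generators** (`ayr.synthetic`) — random cohorts with
  configurable marginal prevalences (defaults calibrated to the published
  AYR 3.0 user population, N=143,657), and deterministic fixture cohorts
  that realize any target confusion matrix or exclusion structure exactly.

## Worked example

Simulate a 10,000-respondent cohort from the default calibration and
validate the AYR labels against the NCCN reference:

```sh
ayr simulate -n 10000 --seed 7 -o cohort.csv
ayr validate cohort.csv --reference nccn --format tsv
```

prints

```
stratum	tp	fp	fn	tn	sensitivity	specificity	ppv	npv	mcnemar_p
overall	4683	457	0	3061	100.0	87.01	91.11	100.0	2.161e-101
```

Reading the row: of 10,000 simulated completions, 1,799 were excluded
(high-risk-by-testing, personal cancer history, or unknown family history)
leaving 8,201 analyzed. Every NCCN-eligible respondent was flagged by the
AYR (`fn = 0`, sensitivity 100%) — that is structural, not luck: the AYR
trigger set contains the NCCN criteria. The 457 false positives are women
whose only trigger is PCOS, chest radiation or an abnormal biopsy — the
factors the AYR checks but NCCN does not — giving specificity 87.01% and
PPV 91.11%; the heavily one-sided discordance makes the McNemar test
reject symmetry (p ≈ 10⁻¹⁰¹). The JSON format (`--format json`) adds the
exclusion counts and raw fractions.

The same analysis is available as a library:

```python
from ayr import CohortConfig, generate, apply_exclusions, confusion, validity
cohort, _ = apply_exclusions(generate(CohortConfig(n=10000, seed=7)))
print(validity(confusion(cohort)).rounded())
# {'sensitivity': 100.0, 'specificity': 87.01, 'ppv': 91.11, 'npv': 100.0}
```

Other subcommands: `ayr classify` (append per-site categories and fired
triggers to a cohort CSV), `ayr reference` (append the NCCN label),
`ayr fixture` (emit a cohort realizing a target confusion matrix). Every
run writes a JSON manifest beside its output with the resolved
configuration, seed and package version. The cohort CSV schema ships as
`src/ayr/data/respondent_schema.json`; the default generator calibration
as `src/ayr/data/table1_defaults.yaml`.

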