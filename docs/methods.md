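# Methods

## The triage model

The AYR instrument reduces hereditary breast/ovarian cancer risk triage to
a deterministic rule set over boolean questionnaire responses. Each
respondent receives a category per cancer site on the ordered scale
average < increased < high:

| rule | fires on | raises |
|---|---|---|
| high-penetrance gene | personal positive test in {BRCA1, BRCA2, MSH2, MLH1, EPCAM, STK11} | both sites → high |
| moderate-penetrance gene | personal positive test in {BRIP1, RAD51C, RAD51D, PMS2, MSH6} | both sites → increased |
| positive relative | relative tested positive ∧ no personal testing history | both sites → increased |
| family-history flags | any of the nine family-history questions | both sites → increased (configurable) |
| chest radiation, abnormal biopsy | personal history | breast → increased |
| PCOS | personal history | ovarian → increased |

High takes precedence; the fired-rule list is recorded in full regardless.
The validation endpoint is the *combined* label, max(breast, ovarian),
collapsed to binary (above average) — the instrument's purpose is to tell
a woman whether to seek genetic counseling for either cancer, not to rank
sites.

The reference classifier re-derives NCCN genetic-testing eligibility from
the same quiz fields: eligible ⇔ moderate-panel positive ∨ positive
relative without personal testing ∨ any family-history flag. It is
deliberately constructed so the two classifiers differ by exactly three
factors — PCOS, chest radiation, abnormal biopsy — which the AYR checks
(they enter the Gail/Tyrer-Cuzick questionnaires) and the NCCN criteria do
not. Two consequences follow structurally and are enforced by exhaustive
tests over all 2^13 trigger combinations:

* **sensitivity is 100% by construction** — the AYR trigger set contains
  the reference criteria, so a reference-positive AYR-negative respondent
  (a false negative) cannot exist;
* specificity < 100% exactly measures the prevalence of extras-only
  respondents among reference-negatives, and moving to the augmented
  reference (NCCN plus the three extras) drives it to 100%.

## Validation analysis

Before comparison the cohort is filtered by the union of three exclusions:
high category via personal genetic testing, personal breast/ovarian cancer
history (nonmelanoma skin cancer never counts), and unknown family
history. Each rule is counted separately and as a union since they
overlap.

Validity measures are the usual 2×2 quantities with the reference as gold
standard; a measure with a zero denominator is reported as absent, never
as 0 or 100. Agreement is tested with McNemar's χ² on the discordant
cells, (b−c)²/(b+c) with 1 df, **without continuity correction**: with a
single discordant pair the uncorrected statistic is 1.0 (p = 0.317,
printing as .32) whereas the corrected one degenerates to 0 (p = 1), and
only the former is consistent with the published stratified results. With
b = c = 0 the statistic is undefined and reported as "no discordant
pairs". Percentages are displayed rounded half-up to 2 decimals; raw
fractions are kept in machine-readable output.

Stratified reports use two partitions: five age bins (18-29, 30-39, 40-49,
50-64, ≥65) and six race/ethnicity strata. The published population tables
list White, African American, Asian, other/multiple, Ashkenazi Jewish and
Hispanic/Latina under one heading with column totals near 100%, so the
package stores a 4-level race response plus two ethnicity booleans and
resolves each respondent to one stratum with precedence Ashkenazi >
Hispanic/Latina > race. This is a reporting convention; the precedence is
isolated in `race_ethnicity_stratum` and easy to change. Published row
totals are never trusted for arithmetic — one printed age-row total is
inconsistent with its own TP + TN — totals are always derived from counts.

## Synthetic cohorts

`generate` draws cohorts factor-by-factor from configured marginals. The
defaults are the published AYR 3.0 user-population marginals (N=143,657):
age-bin weights (58.8 / 22.6 / 12.2 / 5.7 / 0.8%), race/ethnicity weights,
PCOS 9.62%, chest radiation 1.07%, abnormal biopsy 2.45%, dense breasts
16.95%, smoking 15.18%, alcohol ≥2/day 11.26%, <150 min exercise 60.54%,
BMI ~ N(28.22, 7.63²) truncated at 12, personal testing history 3.68%,
family-member testing 24.13%, family history known 86.68% (the complement
of the published unknown-family-history exclusion rate). Family-history
flag prevalences are interpreted as conditional on knowing one's family
history; flags are forced false otherwise, so their unconditional
marginals are ~13% lower than configured. Ages are uniform within bins
with the open bin truncated at 90; matching the published age mean/SD
exactly is not attempted. Where the source tables give no value the
defaults are documented assumptions: positive-relative rate among
family-tested 30%, gene positivity among personally tested 25% high-panel
/ 5% moderate-panel (the published tables are not internally consistent
on this point — the count of high-category respondents exceeds the count
with any personal testing history — so exact calibration is impossible),
three-or-more-cancers family history 5%. Breastfeeding is observed only
in an "ever pregnant" subset (default 41.5% of the cohort, mirroring the
published conditional denominator) and missing elsewhere.

Factors are sampled independently by default; a dependence hook accepts
per-pair odds ratios and resamples the second factor of each pair
conditionally (Plackett joint solution) so that both marginals are
preserved. Generated cohorts therefore emulate the study's *marginal*
structure, not its joint factor distribution, pedigrees or
genotype-phenotype correlation — passing marginal tests says nothing
about real-data joint behavior, which is why the validation metrics are
reproduced from engineered fixtures rather than from random cohorts.

`generate_confusion_cohort` inverts the confusion operator: it emits a
cohort whose AYR-vs-reference matrix is exactly (tp, fp, 0, tn), using
family-history triggers for TP cells, trigger-free respondents for TN,
and — for FP — extras-only respondents (NCCN mode) or high-penetrance
carriers (augmented mode, the one factor that reference still ignores;
such fixtures are meant for exclusion-free use since a high-penetrance
positive would otherwise be excluded). Requests with fn > 0 are refused
with an explicit error: the superset property makes them unrealizable by
the live rules, and the published tables contain none. The single
residual discordant pair in the augmented-reference table has no stated
rule-based origin; it is reproduced here by fixture construction (a
high-penetrance carrier), not by inventing a rule.
`generate_excluded_block` similarly realizes a target exclusion structure,
packing the required overlap between the three rules into pairwise
intersections.

## Numerical and design choices

* Rounding: half-up to 2 decimals for display (`round_half_up`), exact
  fractions elsewhere. The augmented-reference overall specificity of
  40,880/40,881 legitimately displays as 100.00.
* PCOS raises only the ovarian category: the published breast-risk
  population table shows thousands of average-category PCOS cases but
  zero average-category radiation or biopsy cases, so PCOS cannot be a
  breast trigger. Radiation and biopsy are breast-only.
* The positive-relative rule follows the instrument's literal wording "no
  personal history of genetic testing": a woman who tested negative
  herself but has a positive relative is *not* flagged. Clinically
  debatable; documented rather than silently changed.
* Family-history flags raise both site categories by default because the
  endpoint is either-site risk and no per-site split is published;
  `classify(..., family_history_sites=...)` reattributes them.
* Early-onset and three-or-more-cancers are boolean question responses;
  no age or count threshold is computed by the engine — the instrument,
  not the engine, defines them.
* Gene symbols are upper-cased and whitespace-trimmed at read time; any
  symbol outside the two panels is a read error, never silently tiered.
* All randomness flows from one explicit integer seed per call
  (`numpy.random.default_rng`); identical seed and config reproduce a
  cohort exactly.
* Problem sizes: the test suite validates at matrix totals up to the full
  117,595-respondent scale (seconds per run); exhaustive property sweeps
  cover all 2^13 boolean trigger combinations and all confusion matrices
  with total ≤ 12.

## Known limitations

The engine encodes the factor set of the questionnaire, not the on-screen
instrument (wording, branching, free-text pedigrees are out of scope). It
produces no numeric lifetime-risk percentages — triage categories only.
The reference classifier is the quiz-reduced NCCN criteria, not the full
guidelines (no age-at-diagnosis thresholds or pathology subtypes). The
generator's independence default understates real factor clustering;
confidence intervals for validity measures are not computed.
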