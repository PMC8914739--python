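"""Exclusion filtering, confusion matrices, validity measures, McNemar."""

import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from ayr.classifier import ayr_positive
from ayr.concordance import (
    ConfusionMatrix,
    apply_exclusions,
    confusion,
    stratified_validity,
    validity,
)
from ayr.errors import EmptyMatrixError
from ayr.reference import nccn_positive
from ayr.synthetic import CohortConfig, generate, generate_confusion_cohort

from conftest import make_respondent


# ---------------------------------------------------------------- exclusions

def test_no_exclusions_counts_zero():
    cohort = [make_respondent(id=f"r{i}") for i in range(5)]
    kept, report = apply_exclusions(cohort)
    assert len(kept) == 5
    assert report.n_excluded_union == 0
    assert report.n_analyzed == 5


def test_one_respondent_hits_all_three_rules():
    r = make_respondent(
        personal_tested=True,
        personal_positive_genes=frozenset({"BRCA1"}),
        personal_breast_cancer=True,
        family_history_known=False,
    )
    kept, report = apply_exclusions([r])
    assert kept == []
    assert report.n_excluded_high_by_testing == 1
    assert report.n_excluded_personal_cancer == 1
    assert report.n_excluded_unknown_family_history == 1
    assert report.n_excluded_union == 1  # overlap: union < sum of rule counts


def test_moderate_gene_positive_is_not_excluded():
    """Only the high-penetrance (HIGH-tier) testing rule excludes."""
    r = make_respondent(
        personal_tested=True, personal_positive_genes=frozenset({"PMS2"})
    )
    kept, _ = apply_exclusions([r])
    assert kept == [r]


# ------------------------------------------------------------------ confusion

def test_confusion_hand_counted():
    cohort = (
        [make_respondent(id=f"c{i}", fh_ovarian=True) for i in range(2)]       # TP
        + [make_respondent(id="x", pcos=True)]                                  # FP
        + [make_respondent(id=f"n{i}") for i in range(3)]                       # TN
    )
    m = confusion(cohort, ayr_positive, nccn_positive)
    assert (m.tp, m.fp, m.fn, m.tn) == (2, 1, 0, 3)
    assert m.total == len(cohort)


def test_identical_classifiers_have_no_discordance(random_cohort):
    m = confusion(random_cohort, nccn_positive, nccn_positive)
    assert m.fp == 0 and m.fn == 0
    assert m.total == len(random_cohort)


def test_fixture_round_trip_overall_row():
    """The fixture generator inverts the confusion operator exactly, here on
    the full-scale overall matrix recovered from the published counts."""
    cohort = generate_confusion_cohort(72072, 4643, 0, 40880, mode="nccn", seed=9)
    m = confusion(cohort, ayr_positive, nccn_positive)
    assert (m.tp, m.fp, m.fn, m.tn) == (72072, 4643, 0, 40880)


def test_sensitivity_structurally_100_on_random_cohort():
    """fn = 0 on 10,000 random respondents: the AYR trigger set contains the
    reference criteria, so no reference-positive can be AYR-negative."""
    cohort = generate(CohortConfig(n=10000, seed=11))
    kept, _ = apply_exclusions(cohort)
    m = confusion(kept, ayr_positive, nccn_positive)
    assert m.fn == 0


# ------------------------------------------------------------------- validity

def test_validity_formulas_match_brute_force_recount(random_cohort):
    """Measures computed from the matrix agree with a direct per-respondent
    recount of agreement fractions."""
    kept, _ = apply_exclusions(random_cohort)
    labels = [(ayr_positive(r), nccn_positive(r)) for r in kept]
    m = confusion(kept, ayr_positive, nccn_positive)
    v = validity(m)
    ref_pos = [i for i, r in labels if r]
    ref_neg = [i for i, r in labels if not r]
    idx_pos = [r for i, r in labels if i]
    idx_neg = [r for i, r in labels if not i]
    assert v.sensitivity == pytest.approx(100 * sum(ref_pos) / len(ref_pos))
    assert v.specificity == pytest.approx(
        100 * sum(not i for i in ref_neg) / len(ref_neg)
    )
    assert v.ppv == pytest.approx(100 * sum(idx_pos) / len(idx_pos))
    assert v.npv == pytest.approx(100 * sum(not r for r in idx_neg) / len(idx_neg))


def test_perfect_agreement_all_measures_100_mcnemar_undefined():
    v = validity(ConfusionMatrix(tp=10, fp=0, fn=0, tn=10))
    assert v.rounded() == {
        "sensitivity": 100.0, "specificity": 100.0, "ppv": 100.0, "npv": 100.0
    }
    assert v.mcnemar_statistic is None and v.mcnemar_p is None
    assert v.discordant_pairs == (0, 0)
    assert v.to_dict()["note"] == "no discordant pairs"


def test_undefined_denominators_reported_absent():
    v = validity(ConfusionMatrix(tp=0, fp=0, fn=0, tn=5))
    assert v.sensitivity is None and v.ppv is None
    assert v.specificity == 100.0 and v.npv == 100.0


@settings(max_examples=200, derandomize=True, deadline=None)
@given(cells=st.tuples(*[st.integers(0, 10**6)] * 4).filter(lambda c: sum(c) > 0))
def test_validity_invariants_on_arbitrary_matrices(cells):
    """Defined measures lie in [0, 100]; McNemar p in (0, 1]; measures are
    absent exactly when their denominator is zero."""
    tp, fp, fn, tn = cells
    v = validity(ConfusionMatrix(tp, fp, fn, tn))
    for name, den in (
        ("sensitivity", tp + fn), ("specificity", tn + fp),
        ("ppv", tp + fp), ("npv", tn + fn),
    ):
        value = getattr(v, name)
        assert (value is None) == (den == 0)
        if value is not None:
            assert 0.0 <= value <= 100.0
    if fn + fp == 0:
        assert v.mcnemar_p is None
    else:
        assert 0.0 <= v.mcnemar_p <= 1.0
        assert v.mcnemar_statistic >= 0.0


def test_empty_matrix_rejected():
    with pytest.raises(EmptyMatrixError):
        validity(ConfusionMatrix(0, 0, 0, 0))


@pytest.mark.parametrize(
    "b,c,stat,p",
    [
        (0, 1, 1.0, 0.3173),   # single discordant pair
        (3, 3, 0.0, 1.0),      # balanced discordance
        (0, 4643, 4643.0, 0.0),
    ],
)
def test_mcnemar_uncorrected(b, c, stat, p):
    v = validity(ConfusionMatrix(tp=10, fp=c, fn=b, tn=10))
    assert v.mcnemar_statistic == pytest.approx(stat)
    assert v.mcnemar_p == pytest.approx(p, abs=1e-3)
    assert v.discordant_pairs == (b, c)


@pytest.mark.parametrize("b,c", [(0, 1), (2, 7), (5, 5), (1, 0)])
def test_mcnemar_against_statsmodels(b, c):
    """Cross-check the uncorrected chi-square McNemar against statsmodels."""
    v = validity(ConfusionMatrix(tp=20, fp=c, fn=b, tn=30))
    oracle = sm_mcnemar([[20, b], [c, 30]], exact=False, correction=False)
    assert v.mcnemar_statistic == pytest.approx(float(oracle.statistic))
    assert v.mcnemar_p == pytest.approx(float(oracle.pvalue))


# ----------------------------------------------------------------- stratified

def test_single_stratum_equals_overall():
    cohort = generate_confusion_cohort(8, 3, 0, 9, seed=1, stratum="asian")
    overall = validity(confusion(cohort, ayr_positive, nccn_positive))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # five empty strata
        per = stratified_validity(cohort, ayr_positive, nccn_positive,
                                  strata="race_ethnicity")
    assert set(per) == {"asian"}
    _, report = per["asian"]
    assert report == overall


@pytest.mark.parametrize("strata", ["race_ethnicity", "age_group"])
def test_partition_conservation(random_cohort, strata):
    """Per-stratum matrices sum to the overall matrix."""
    kept, _ = apply_exclusions(random_cohort)
    overall = confusion(kept, ayr_positive, nccn_positive)
    per = stratified_validity(kept, ayr_positive, nccn_positive, strata=strata)
    total = ConfusionMatrix(0, 0, 0, 0)
    for m, _ in per.values():
        total = total + m
    assert total == overall


def test_empty_stratum_omitted_with_warning():
    cohort = generate_confusion_cohort(2, 1, 0, 2, stratum="white")
    with pytest.warns(UserWarning, match="no members"):
        per = stratified_validity(cohort, strata="race_ethnicity")
    assert set(per) == {"white"}
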