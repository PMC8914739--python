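"""Concordance validation of the AYR classifier against a reference.

Pipeline: exclusion filtering, 2x2 confusion matrix of the binary AYR label
(combined category above AVERAGE) against a reference label, validity
measures (sensitivity, specificity, PPV, NPV) and the McNemar test of
agreement, overall or stratified by race/ethnicity or age group.

Exclusion rules (applied as a union; a respondent may hit several):

1. HIGH category via personal genetic testing (a personal positive on the
   high-penetrance panel) — these women already know their status;
2. personal history of breast or ovarian cancer (nonmelanoma skin cancer is
   never recorded as cancer) — the tool targets prevention, not survivors;
3. no knowledge of family history — neither classifier is meaningful.

The McNemar statistic is computed on the discordant cells b (reference
positive, index negative) and c (reference negative, index positive) as
(b - c)^2 / (b + c), chi-squared with 1 df, without continuity correction.
With no discordant pairs the statistic and p-value are undefined and
reported as absent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Sequence

from scipy.stats import chi2

from .classifier import ayr_positive
from .cohort import (
    HIGH_PENETRANCE,
    RACE_ETHNICITY_STRATA,
    AgeGroup,
    Respondent,
    race_ethnicity_stratum,
)
from .errors import AyrError, EmptyMatrixError
from .reference import nccn_plus_positive, nccn_positive

__all__ = [
    "ExclusionReport",
    "ConfusionMatrix",
    "ValidityReport",
    "apply_exclusions",
    "confusion",
    "validity",
    "stratified_validity",
    "REFERENCE_MODES",
    "round_half_up",
]

Classifier = Callable[[Respondent], bool]

#: Reference modes selectable from the CLI and the validation API.
REFERENCE_MODES: dict[str, Classifier] = {
    "nccn": nccn_positive,
    "nccn_plus_extras": nccn_plus_positive,
}


def round_half_up(x: float, places: int = 2) -> float:
    """Round half away from zero to ``places`` decimals (display convention)."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(slots=True)
class ExclusionReport:
    """Counts for the three exclusion rules and their union."""

    n_input: int = 0
    n_excluded_high_by_testing: int = 0
    n_excluded_personal_cancer: int = 0
    n_excluded_unknown_family_history: int = 0
    n_excluded_union: int = 0

    @property
    def n_analyzed(self) -> int:
        return self.n_input - self.n_excluded_union

    def to_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_excluded_high_by_testing": self.n_excluded_high_by_testing,
            "n_excluded_personal_cancer": self.n_excluded_personal_cancer,
            "n_excluded_unknown_family_history": self.n_excluded_unknown_family_history,
            "n_excluded_union": self.n_excluded_union,
            "n_analyzed": self.n_analyzed,
        }


def apply_exclusions(
    cohort: Sequence[Respondent],
) -> tuple[list[Respondent], ExclusionReport]:
    """Filter a cohort by the three exclusion rules (union) and count each."""
    report = ExclusionReport(n_input=len(cohort))
    kept: list[Respondent] = []
    for r in cohort:
        high_by_testing = bool(r.personal_positive_genes & HIGH_PENETRANCE)
        personal_cancer = r.personal_breast_cancer or r.personal_ovarian_cancer
        unknown_fh = not r.family_history_known
        if high_by_testing:
            report.n_excluded_high_by_testing += 1
        if personal_cancer:
            report.n_excluded_personal_cancer += 1
        if unknown_fh:
            report.n_excluded_unknown_family_history += 1
        if high_by_testing or personal_cancer or unknown_fh:
            report.n_excluded_union += 1
        else:
            kept.append(r)
    return kept, report


@dataclass(frozen=True, slots=True)
class ConfusionMatrix:
    """2x2 agreement table; the reference classifier is the gold standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise AyrError("confusion-matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )

    def to_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


def confusion(
    cohort: Sequence[Respondent],
    index: Classifier = ayr_positive,
    reference: Classifier = nccn_positive,
) -> ConfusionMatrix:
    """Cross-classify every respondent by the index and reference labels."""
    if not cohort:
        warnings.warn("confusion matrix computed on an empty cohort", stacklevel=2)
    tp = fp = fn = tn = 0
    for r in cohort:
        idx = index(r)
        ref = reference(r)
        if idx and ref:
            tp += 1
        elif idx and not ref:
            fp += 1
        elif not idx and ref:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp, fp, fn, tn)


@dataclass(frozen=True, slots=True)
class ValidityReport:
    """Validity measures for one stratum.

    Percentages are exact fractions times 100; use :meth:`rounded` for the
    2-decimal display convention.  A measure whose denominator is zero is
    ``None`` (absent), never 0 or 100.  ``discordant_pairs`` is (b, c) with
    b = reference-positive/index-negative and c = the reverse.
    """

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    mcnemar_statistic: float | None
    mcnemar_p: float | None
    discordant_pairs: tuple[int, int]

    def rounded(self, places: int = 2) -> dict[str, float | None]:
        out: dict[str, float | None] = {}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            value = getattr(self, name)
            out[name] = None if value is None else round_half_up(value, places)
        return out

    def to_dict(self) -> dict[str, object]:
        d: dict[str, object] = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "mcnemar_statistic": self.mcnemar_statistic,
            "mcnemar_p": self.mcnemar_p,
            "discordant_pairs": list(self.discordant_pairs),
            "rounded": self.rounded(),
        }
        if self.discordant_pairs == (0, 0):
            d["note"] = "no discordant pairs"
        return d


def _ratio_pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def validity(m: ConfusionMatrix) -> ValidityReport:
    """Sensitivity/specificity/PPV/NPV and the uncorrected McNemar test."""
    if m.total == 0:
        raise EmptyMatrixError("validity measures undefined for an empty matrix")
    b, c = m.fn, m.fp
    if b + c == 0:
        stat = p = None
    else:
        stat = (b - c) ** 2 / (b + c)
        p = float(chi2.sf(stat, df=1))
    return ValidityReport(
        sensitivity=_ratio_pct(m.tp, m.tp + m.fn),
        specificity=_ratio_pct(m.tn, m.tn + m.fp),
        ppv=_ratio_pct(m.tp, m.tp + m.fp),
        npv=_ratio_pct(m.tn, m.tn + m.fn),
        mcnemar_statistic=stat,
        mcnemar_p=p,
        discordant_pairs=(b, c),
    )


def _stratum_key(strata: str) -> Callable[[Respondent], str]:
    if strata == "race_ethnicity":
        return race_ethnicity_stratum
    if strata == "age_group":
        return lambda r: r.age_group.value
    raise AyrError(
        f"unknown strata specification {strata!r}; "
        "expected 'race_ethnicity' or 'age_group'"
    )


def _stratum_order(strata: str) -> tuple[str, ...]:
    if strata == "race_ethnicity":
        return RACE_ETHNICITY_STRATA
    return tuple(g.value for g in AgeGroup)


def stratified_validity(
    cohort: Sequence[Respondent],
    index: Classifier = ayr_positive,
    reference: Classifier = nccn_positive,
    strata: str = "race_ethnicity",
) -> dict[str, tuple[ConfusionMatrix, ValidityReport]]:
    """Per-stratum confusion matrices and validity reports.

    Both strata specifications partition the cohort, so the per-stratum
    matrices sum to the overall matrix.  Empty strata are omitted with a
    warning.
    """
    key = _stratum_key(strata)
    groups: dict[str, list[Respondent]] = {}
    for r in cohort:
        groups.setdefault(key(r), []).append(r)
    out: dict[str, tuple[ConfusionMatrix, ValidityReport]] = {}
    for label in _stratum_order(strata):
        members = groups.pop(label, [])
        if not members:
            warnings.warn(f"stratum {label!r} has no members; omitted", stacklevel=2)
            continue
        m = confusion(members, index, reference)
        out[label] = (m, validity(m))
    return out
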