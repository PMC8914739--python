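"""Respondent records, cohort CSV input/output and schema validation.

A *respondent* is one completion of the 26-question risk quiz: demographics,
personal cancer history, personal and family genetic-testing results, boolean
family-history flags, personal risk factors (chest radiation, abnormal breast
biopsy, PCOS, dense breasts) and health behaviors.  The cohort file format is
a UTF-8 comma-separated file with a fixed header (``COLUMNS``); booleans are
encoded 0/1 and the set of personally tested-positive genes is a single
semicolon-joined field ("" = tested negative or untested).

Structural invariants every record must satisfy:

* a non-empty gene-positive set implies a personal genetic-testing history;
* a positive family member implies a family genetic-testing history;
* when family history is unknown, every family-history flag is false;
* age is at least 18 (the instrument is restricted to adult women).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import CohortReadError, InvariantError, SchemaError

__all__ = [
    "HIGH_PENETRANCE",
    "MODERATE_LOWER",
    "KNOWN_GENES",
    "RACES",
    "FH_FLAGS",
    "COLUMNS",
    "AgeGroup",
    "Respondent",
    "ReadReport",
    "age_group",
    "read_cohort",
    "write_cohort",
]

#: Genes whose personal positive test marks hereditary breast/ovarian cancer
#: syndrome (BRCA1/2), Lynch syndrome (MSH2/MLH1/EPCAM) or Peutz-Jeghers
#: syndrome (STK11) — the high-penetrance panel.
HIGH_PENETRANCE = frozenset({"BRCA1", "BRCA2", "MSH2", "MLH1", "EPCAM", "STK11"})

#: Moderate-to-lower penetrance panel.
MODERATE_LOWER = frozenset({"BRIP1", "RAD51C", "RAD51D", "PMS2", "MSH6"})

KNOWN_GENES = HIGH_PENETRANCE | MODERATE_LOWER

RACES = ("white", "african_american", "asian", "other_or_multiple")

#: The nine boolean family-history questions.
FH_FLAGS = (
    "fh_early_onset_breast",
    "fh_triple_negative",
    "fh_multiple_breast_same_relative",
    "fh_multiple_breast_one_le50",
    "fh_male_breast",
    "fh_ovarian",
    "fh_metastatic_prostate",
    "fh_pancreatic",
    "fh_three_or_more_cancers_one_side",
)


class AgeGroup(enum.Enum):
    """Five exhaustive, disjoint age bins over the integers >= 18."""

    A18_29 = "18-29"
    A30_39 = "30-39"
    A40_49 = "40-49"
    A50_64 = "50-64"
    GE65 = "≥65"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def age_group(age: int) -> AgeGroup:
    """Map an integer age in years to its reporting bin.

    Raises :class:`InvariantError` for ages below 18: the instrument is
    restricted to women aged >= 18 years.
    """
    if age < 18:
        raise InvariantError(f"age must be >= 18, got {age}")
    if age <= 29:
        return AgeGroup.A18_29
    if age <= 39:
        return AgeGroup.A30_39
    if age <= 49:
        return AgeGroup.A40_49
    if age <= 64:
        return AgeGroup.A50_64
    return AgeGroup.GE65


@dataclass(slots=True)
class Respondent:
    """One quiz completion."""

    id: str
    age: int
    race: str = "white"
    ashkenazi_jewish: bool = False
    hispanic_latina: bool = False
    # personal cancer history; nonmelanoma skin cancer is never recorded here
    personal_breast_cancer: bool = False
    personal_ovarian_cancer: bool = False
    # genetic testing
    personal_tested: bool = False
    personal_positive_genes: frozenset[str] = field(default_factory=frozenset)
    family_member_tested: bool = False
    family_member_positive: bool = False
    # family history
    family_history_known: bool = True
    fh_early_onset_breast: bool = False
    fh_triple_negative: bool = False
    fh_multiple_breast_same_relative: bool = False
    fh_multiple_breast_one_le50: bool = False
    fh_male_breast: bool = False
    fh_ovarian: bool = False
    fh_metastatic_prostate: bool = False
    fh_pancreatic: bool = False
    fh_three_or_more_cancers_one_side: bool = False
    # personal risk factors
    chest_radiation: bool = False
    abnormal_biopsy: bool = False
    pcos: bool = False
    dense_breasts: bool = False
    # health behaviors (never used for classification)
    bmi: float = 28.0
    alcohol_ge2_per_day: bool = False
    exercise_lt150_min: bool = False
    current_smoker: bool = False
    breastfed: bool | None = None

    def violations(self) -> list[str]:
        """Return the list of violated structural invariants (empty if valid)."""
        problems: list[str] = []
        if self.age < 18:
            problems.append(f"age {self.age} < 18")
        if self.race not in RACES:
            problems.append(f"unknown race {self.race!r}")
        unknown = self.personal_positive_genes - KNOWN_GENES
        if unknown:
            problems.append(
                f"unknown gene symbol(s) {sorted(unknown)}; accepted: "
                f"{sorted(KNOWN_GENES)}"
            )
        if self.personal_positive_genes and not self.personal_tested:
            problems.append("positive genes recorded without personal testing")
        if self.family_member_positive and not self.family_member_tested:
            problems.append("positive family member without family testing")
        if not self.family_history_known:
            for flag in FH_FLAGS:
                if getattr(self, flag):
                    problems.append(f"{flag} set while family history unknown")
        if self.bmi <= 0:
            problems.append(f"bmi {self.bmi} must be positive")
        return problems

    def validate(self) -> None:
        problems = self.violations()
        if problems:
            raise InvariantError("; ".join(problems))

    @property
    def age_group(self) -> AgeGroup:
        return age_group(self.age)


#: Published column order of the cohort CSV.
COLUMNS = tuple(f.name for f in fields(Respondent))

_BOOL_FIELDS = tuple(
    f.name for f in fields(Respondent) if f.type in ("bool", bool)
)


@dataclass
class ReadReport:
    """Per-file accounting returned by :func:`read_cohort`."""

    n_rows: int = 0
    n_loaded: int = 0
    n_dropped: int = 0
    errors: list[str] = field(default_factory=list)


def _parse_bool(raw: str, column: str) -> bool:
    if raw == "0":
        return False
    if raw == "1":
        return True
    raise ValueError(f"column {column!r}: expected 0/1, got {raw!r}")


def _parse_genes(raw: str) -> frozenset[str]:
    symbols = frozenset(s.strip().upper() for s in raw.split(";") if s.strip())
    unknown = symbols - KNOWN_GENES
    if unknown:
        raise ValueError(
            f"unknown gene symbol(s) {sorted(unknown)}; accepted symbols: "
            f"{sorted(KNOWN_GENES)}"
        )
    return symbols


def _parse_row(row: dict[str, str]) -> Respondent:
    kwargs: dict[str, object] = {"id": row["id"]}
    kwargs["age"] = int(row["age"])
    race = row["race"].strip()
    if race not in RACES:
        raise ValueError(f"column 'race': expected one of {RACES}, got {race!r}")
    kwargs["race"] = race
    kwargs["personal_positive_genes"] = _parse_genes(row["personal_positive_genes"])
    kwargs["bmi"] = float(row["bmi"])
    raw_breastfed = row["breastfed"].strip()
    kwargs["breastfed"] = (
        None if raw_breastfed == "" else _parse_bool(raw_breastfed, "breastfed")
    )
    for name in _BOOL_FIELDS:
        kwargs[name] = _parse_bool(row[name].strip(), name)
    return Respondent(**kwargs)  # type: ignore[arg-type]


def read_cohort(
    path: str | Path, strict: bool = False
) -> tuple[list[Respondent], ReadReport]:
    """Read a cohort CSV.

    In strict mode the first malformed or invariant-violating row aborts the
    read with :class:`CohortReadError` (the message names the 1-based file
    line).  Otherwise offending rows are dropped and counted in the returned
    :class:`ReadReport`.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    cohort: list[Respondent] = []
    report = ReadReport(n_rows=len(frame))
    for i, row in enumerate(frame.to_dict("records")):
        line = i + 2  # header is line 1
        try:
            respondent = _parse_row(row)
            respondent.validate()
        except (ValueError, InvariantError) as exc:
            if strict:
                raise CohortReadError(str(exc), row=line) from exc
            report.n_dropped += 1
            report.errors.append(f"row {line}: {exc}")
            continue
        cohort.append(respondent)
    report.n_loaded = len(cohort)
    return cohort, report


def _format_value(respondent: Respondent, name: str) -> object:
    value = getattr(respondent, name)
    if name == "personal_positive_genes":
        return ";".join(sorted(value))
    if name == "breastfed":
        return "" if value is None else int(value)
    if isinstance(value, bool):
        return int(value)
    return value


def write_cohort(cohort: Iterable[Respondent], path: str | Path) -> None:
    """Write a cohort to CSV in the published column order."""
    rows = [{c: _format_value(r, c) for c in COLUMNS} for r in cohort]
    frame = pd.DataFrame(rows, columns=list(COLUMNS))
    frame.to_csv(path, index=False)


def race_ethnicity_stratum(respondent: Respondent) -> str:
    """Resolve a respondent to exactly one of six race/ethnicity strata.

    Precedence: Ashkenazi Jewish ethnicity, then Hispanic/Latina ethnicity,
    then the four-level race response.  The order is a reporting convention,
    not a statement about identity; it makes the six strata a partition.
    """
    if respondent.ashkenazi_jewish:
        return "ashkenazi_jewish"
    if respondent.hispanic_latina:
        return "hispanic_latina"
    return respondent.race


RACE_ETHNICITY_STRATA = (
    "white",
    "african_american",
    "asian",
    "other_or_multiple",
    "ashkenazi_jewish",
    "hispanic_latina",
)


def cohort_to_frame(cohort: Sequence[Respondent]) -> pd.DataFrame:
    """Tabular view of a cohort (one row per respondent, published columns)."""
    rows = [{c: _format_value(r, c) for c in COLUMNS} for r in cohort]
    return pd.DataFrame(rows, columns=list(COLUMNS))
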