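"""The AYR risk algorithm.

Each respondent receives a breast and an ovarian risk category on the ordered
scale AVERAGE < INCREASED < HIGH, plus the list of rule identifiers that
fired.  The rules:

* HIGH (both sites) — a personal positive test for a high-penetrance gene
  (BRCA1/2, MSH2, MLH1, EPCAM, STK11).  HIGH takes precedence over every
  other rule, but the trigger list still records every rule that fired.
* INCREASED — any of: a personal positive test for a moderate/lower
  penetrance gene; a relative with a positive gene test combined with no
  personal testing history; any family-history flag; or the site-specific
  extra factors drawn from the Gail and Tyrer-Cuzick questionnaires —
  childhood chest radiation or abnormal breast biopsy (breast site),
  polycystic ovary syndrome (ovarian site).
* AVERAGE otherwise.

Dense breasts and the health behaviors (BMI, alcohol, exercise, smoking,
breastfeeding) are descriptive only and never change a category.

The family-history flags raise both site categories by default because the
validation endpoint is "increased risk for either breast or ovarian cancer";
per-site attribution is configurable via ``family_history_sites``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .cohort import FH_FLAGS, HIGH_PENETRANCE, MODERATE_LOWER, Respondent

__all__ = ["RiskCategory", "RiskAssessment", "classify", "ayr_positive"]


class RiskCategory(enum.IntEnum):
    """Ordered risk tier; the integer order is the clinical escalation order."""

    AVERAGE = 0
    INCREASED = 1
    HIGH = 2

    def __str__(self) -> str:
        return self.name.lower()


# rule identifiers
GENE_HIGH = "personal_high_penetrance_gene"
GENE_MODERATE = "personal_moderate_penetrance_gene"
RELATIVE_POSITIVE = "relative_positive_untested"
CHEST_RADIATION = "chest_radiation"
ABNORMAL_BIOPSY = "abnormal_biopsy"
PCOS = "pcos"


@dataclass(frozen=True, slots=True)
class RiskAssessment:
    """Per-respondent classification result."""

    respondent_id: str
    breast: RiskCategory
    ovarian: RiskCategory
    triggers: tuple[str, ...]

    @property
    def combined(self) -> RiskCategory:
        """The either-site endpoint used for validation."""
        return max(self.breast, self.ovarian)


def classify(
    respondent: Respondent,
    family_history_sites: tuple[str, ...] = ("breast", "ovarian"),
) -> RiskAssessment:
    """Run the AYR rules on one respondent.

    ``family_history_sites`` controls which site categories a family-history
    flag raises; the default raises both, matching the either-site endpoint.
    Raises :class:`~ayr.errors.InvariantError` on an invalid record.
    """
    respondent.validate()

    triggers: list[str] = []
    breast = RiskCategory.AVERAGE
    ovarian = RiskCategory.AVERAGE

    def raise_site(site: str, level: RiskCategory) -> None:
        nonlocal breast, ovarian
        if site == "breast":
            breast = max(breast, level)
        else:
            ovarian = max(ovarian, level)

    genes = respondent.personal_positive_genes
    high_gene = bool(genes & HIGH_PENETRANCE)
    if high_gene:
        triggers.append(GENE_HIGH)
    if genes & MODERATE_LOWER:
        triggers.append(GENE_MODERATE)
        raise_site("breast", RiskCategory.INCREASED)
        raise_site("ovarian", RiskCategory.INCREASED)
    if respondent.family_member_positive and not respondent.personal_tested:
        triggers.append(RELATIVE_POSITIVE)
        raise_site("breast", RiskCategory.INCREASED)
        raise_site("ovarian", RiskCategory.INCREASED)
    for flag in FH_FLAGS:
        if getattr(respondent, flag):
            triggers.append(flag)
            for site in family_history_sites:
                raise_site(site, RiskCategory.INCREASED)
    if respondent.chest_radiation:
        triggers.append(CHEST_RADIATION)
        raise_site("breast", RiskCategory.INCREASED)
    if respondent.abnormal_biopsy:
        triggers.append(ABNORMAL_BIOPSY)
        raise_site("breast", RiskCategory.INCREASED)
    if respondent.pcos:
        triggers.append(PCOS)
        raise_site("ovarian", RiskCategory.INCREASED)

    if high_gene:
        breast = RiskCategory.HIGH
        ovarian = RiskCategory.HIGH

    return RiskAssessment(
        respondent_id=respondent.id,
        breast=breast,
        ovarian=ovarian,
        triggers=tuple(triggers),
    )


def ayr_positive(respondent: Respondent) -> bool:
    """Binary index label for concordance: combined category above AVERAGE."""
    return classify(respondent).combined >= RiskCategory.INCREASED
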