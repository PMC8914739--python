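"""Independently constructed NCCN-criteria reference classifier.

The NCCN genetic/familial high-risk assessment criteria, reduced to the
boolean factors the quiz collects, flag a woman as eligible for genetic
counseling/testing when she reports (1) a family history of BRCA1/2 or other
gene variants — realized here as either a positive relative with no personal
testing history or a personal positive test on the moderate/lower penetrance
panel — (2) a family history of high-risk cancers (triple-negative, male
breast, early-onset, ovarian, metastatic prostate, pancreatic, multiple
primaries) or (3) three or more cancers on one side of the family.

Chest radiation, abnormal breast biopsy and PCOS are deliberately ignored:
they are the extra factors the AYR adds beyond the NCCN criteria.  The
augmented variant :func:`nccn_plus_extras` adds exactly those three, so the
two reference modes bracket the AYR increased tier from below and above.
"""

from __future__ import annotations

import enum

from .cohort import FH_FLAGS, MODERATE_LOWER, Respondent

__all__ = [
    "ReferenceLabel",
    "nccn_eligible",
    "nccn_plus_extras",
    "nccn_positive",
    "nccn_plus_positive",
]


class ReferenceLabel(enum.Enum):
    ELIGIBLE = "eligible"          # increased risk under the reference rules
    NOT_ELIGIBLE = "not_eligible"  # average risk

    def __bool__(self) -> bool:
        return self is ReferenceLabel.ELIGIBLE


def nccn_eligible(respondent: Respondent) -> ReferenceLabel:
    """Reference label from the quiz-reduced NCCN criteria only."""
    if respondent.personal_positive_genes & MODERATE_LOWER:
        return ReferenceLabel.ELIGIBLE
    if respondent.family_member_positive and not respondent.personal_tested:
        return ReferenceLabel.ELIGIBLE
    if any(getattr(respondent, flag) for flag in FH_FLAGS):
        return ReferenceLabel.ELIGIBLE
    return ReferenceLabel.NOT_ELIGIBLE


def nccn_plus_extras(respondent: Respondent) -> ReferenceLabel:
    """Reference label from the NCCN criteria plus PCOS, childhood chest
    radiation and abnormal breast biopsy (the AYR-only factors)."""
    if nccn_eligible(respondent) is ReferenceLabel.ELIGIBLE:
        return ReferenceLabel.ELIGIBLE
    if respondent.chest_radiation or respondent.abnormal_biopsy or respondent.pcos:
        return ReferenceLabel.ELIGIBLE
    return ReferenceLabel.NOT_ELIGIBLE


def nccn_positive(respondent: Respondent) -> bool:
    return bool(nccn_eligible(respondent))


def nccn_plus_positive(respondent: Respondent) -> bool:
    return bool(nccn_plus_extras(respondent))
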