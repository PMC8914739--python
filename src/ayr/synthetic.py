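"""Synthetic cohort generators.

Two kinds of generator live here:

* :func:`generate` draws random cohorts with configurable marginal
  prevalences.  The defaults in :class:`CohortConfig` are calibrated to the
  published characteristics of the AYR 3.0 user population (N=143,657): for
  example PCOS 9.62%, childhood chest radiation 1.07%, abnormal breast
  biopsy 2.45%, current smoking 15.18%, mean BMI 28.22 (SD 7.63).  Factors
  are sampled independently unless per-pair odds ratios are supplied.

* :func:`generate_confusion_cohort` and :func:`generate_excluded_block`
  build deterministic fixture cohorts that realize an arbitrary target
  confusion matrix, or a target exclusion structure, exactly — the device
  that makes every published concordance table reproducible from its
  printed counts, because no respondent-level data are deposited.

All randomness flows through one integer seed per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import FH_FLAGS, HIGH_PENETRANCE, MODERATE_LOWER, Respondent
from .errors import ConfigError, UnrealizableFixtureError

__all__ = [
    "CohortConfig",
    "generate",
    "generate_confusion_cohort",
    "generate_excluded_block",
]

AGE_BIN_RANGES = {
    "18-29": (18, 29),
    "30-39": (30, 39),
    "40-49": (40, 49),
    "50-64": (50, 64),
    "≥65": (65, 90),  # open bin truncated at 90
}

#: (race, ashkenazi_jewish, hispanic_latina) realization of each stratum.
#: The two ethnicity strata carry a white race response so that the
#: precedence rule (Ashkenazi > Hispanic/Latina > race) recovers the stratum.
STRATUM_FIELDS = {
    "white": ("white", False, False),
    "african_american": ("african_american", False, False),
    "asian": ("asian", False, False),
    "other_or_multiple": ("other_or_multiple", False, False),
    "ashkenazi_jewish": ("white", True, False),
    "hispanic_latina": ("white", False, True),
}


@dataclass
class CohortConfig:
    """Marginal prevalences and distributional parameters for :func:`generate`.

    Probabilities are per-respondent Bernoulli marginals.  Family-history
    flag prevalences are conditional on knowing one's family history (flags
    are forced false otherwise).  Gene-positivity probabilities are
    conditional on a personal testing history.  ``breastfed`` is observed
    only in an "ever pregnant" subset and missing elsewhere.
    """

    n: int = 1000
    seed: int = 0

    # demographics
    age_bin_weights: dict[str, float] = field(
        default_factory=lambda: {
            "18-29": 0.5882,
            "30-39": 0.2256,
            "40-49": 0.1215,
            "50-64": 0.0567,
            "≥65": 0.0080,
        }
    )
    race_ethnicity_weights: dict[str, float] = field(
        default_factory=lambda: {
            "white": 0.6768,
            "african_american": 0.0348,
            "asian": 0.0311,
            "other_or_multiple": 0.1561,
            "ashkenazi_jewish": 0.0050,
            "hispanic_latina": 0.0962,
        }
    )

    # personal cancer history (mutually exclusive categories)
    p_breast_cancer_only: float = 0.0320
    p_ovarian_cancer_only: float = 0.0089
    p_breast_and_ovarian: float = 0.0082

    # genetic testing
    p_personal_tested: float = 0.0368
    p_high_gene_given_tested: float = 0.25
    p_moderate_gene_given_tested: float = 0.05
    p_family_member_tested: float = 0.2413
    p_family_positive_given_tested: float = 0.30

    # family history
    p_family_history_known: float = 0.8668
    fh_prevalences: dict[str, float] = field(
        default_factory=lambda: {
            "fh_early_onset_breast": 0.1815,
            "fh_triple_negative": 0.0407,
            "fh_multiple_breast_same_relative": 0.1145,
            "fh_multiple_breast_one_le50": 0.0955,
            "fh_male_breast": 0.0070,
            "fh_ovarian": 0.1163,
            "fh_metastatic_prostate": 0.0544,
            "fh_pancreatic": 0.0817,
            "fh_three_or_more_cancers_one_side": 0.05,
        }
    )

    # personal risk factors
    p_chest_radiation: float = 0.0107
    p_abnormal_biopsy: float = 0.0245
    p_pcos: float = 0.0962
    p_dense_breasts: float = 0.1695

    # health behaviors (classification-inert)
    p_alcohol_ge2_per_day: float = 0.1126
    p_exercise_lt150_min: float = 0.6054
    p_current_smoker: float = 0.1518
    p_ever_pregnant: float = 0.415
    p_breastfed_given_pregnant: float = 0.415
    bmi_mean: float = 28.22
    bmi_sd: float = 7.63
    bmi_min: float = 12.0

    #: Optional dependence hook: {(factor_a, factor_b): odds_ratio}.  Factor b
    #: is resampled conditionally on factor a so that both marginals are kept
    #: while the pairwise odds ratio matches.  Each factor may appear in at
    #: most one pair; factors must be simple boolean fields.
    pairwise_odds_ratios: dict[tuple[str, str], float] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "CohortConfig":
        """Build a config from a plain mapping (e.g. parsed YAML).

        ``pairwise_odds_ratios`` is accepted as a list of ``[factor_a,
        factor_b, odds_ratio]`` triples, since YAML mappings cannot carry
        tuple keys.
        """
        data = dict(data)
        unknown = set(data) - {f.name for f in _config_fields()}
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        pairs = data.pop("pairwise_odds_ratios", None)
        config = cls(**data)
        if pairs:
            try:
                config.pairwise_odds_ratios = {
                    (str(a), str(b)): float(odds) for a, b, odds in pairs
                }
            except (TypeError, ValueError) as exc:
                raise ConfigError(
                    "pairwise_odds_ratios must be [factor_a, factor_b, odds] triples"
                ) from exc
        config.validate()
        return config

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def validate(self) -> None:
        if self.n < 0:
            raise ConfigError(f"n must be >= 0, got {self.n}")
        for name, value in self.__dict__.items():
            if name.startswith("p_") and not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}={value} outside [0, 1]")
        if self.p_breast_cancer_only + self.p_ovarian_cancer_only + self.p_breast_and_ovarian > 1:
            raise ConfigError("personal-cancer category probabilities exceed 1")
        if self.p_high_gene_given_tested + self.p_moderate_gene_given_tested > 1:
            raise ConfigError("gene-positivity probabilities exceed 1")
        for label, p in self.fh_prevalences.items():
            if label not in FH_FLAGS:
                raise ConfigError(f"unknown family-history flag {label!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"fh_prevalences[{label!r}]={p} outside [0, 1]")
        for name, weights, labels in (
            ("age_bin_weights", self.age_bin_weights, AGE_BIN_RANGES),
            ("race_ethnicity_weights", self.race_ethnicity_weights, STRATUM_FIELDS),
        ):
            if set(weights) != set(labels):
                raise ConfigError(f"{name} must have keys {sorted(labels)}")
            if any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
                raise ConfigError(f"{name} must be non-negative with positive sum")
        if self.bmi_sd <= 0 or self.bmi_min <= 0:
            raise ConfigError("bmi_sd and bmi_min must be positive")
        seen: set[str] = set()
        for (a, b), odds in self.pairwise_odds_ratios.items():
            if odds <= 0:
                raise ConfigError(f"odds ratio for ({a}, {b}) must be positive")
            for f in (a, b):
                if f in seen:
                    raise ConfigError(f"factor {f!r} appears in more than one pair")
                seen.add(f)


def _config_fields():
    from dataclasses import fields as dc_fields

    return dc_fields(CohortConfig)


def _joint_p11(pa: float, pb: float, odds: float) -> float:
    """P(a=1, b=1) with given marginals and odds ratio (Plackett solution)."""
    if math.isclose(odds, 1.0):
        return pa * pb
    s = 1.0 + (pa + pb) * (odds - 1.0)
    disc = s * s - 4.0 * odds * (odds - 1.0) * pa * pb
    return (s - math.sqrt(max(disc, 0.0))) / (2.0 * (odds - 1.0))


def generate(config: CohortConfig) -> list[Respondent]:
    """Draw a random cohort of ``config.n`` respondents.

    Deterministic for a fixed (seed, config); all respondent invariants are
    enforced by construction (gene positives only among the tested, flags
    cleared when family history is unknown).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    if n == 0:
        return []

    # demographics
    strata = list(config.race_ethnicity_weights)
    sw = np.array([config.race_ethnicity_weights[s] for s in strata], dtype=float)
    stratum_idx = rng.choice(len(strata), size=n, p=sw / sw.sum())
    bins = list(config.age_bin_weights)
    bw = np.array([config.age_bin_weights[b] for b in bins], dtype=float)
    bin_idx = rng.choice(len(bins), size=n, p=bw / bw.sum())
    lo = np.array([AGE_BIN_RANGES[b][0] for b in bins])[bin_idx]
    hi = np.array([AGE_BIN_RANGES[b][1] for b in bins])[bin_idx]
    ages = rng.integers(lo, hi + 1)

    # simple boolean factors, with the optional odds-ratio coupling
    factor_p = {
        "chest_radiation": config.p_chest_radiation,
        "abnormal_biopsy": config.p_abnormal_biopsy,
        "pcos": config.p_pcos,
        "dense_breasts": config.p_dense_breasts,
        "alcohol_ge2_per_day": config.p_alcohol_ge2_per_day,
        "exercise_lt150_min": config.p_exercise_lt150_min,
        "current_smoker": config.p_current_smoker,
        **config.fh_prevalences,
    }
    coupled = {f for pair in config.pairwise_odds_ratios for f in pair}
    draws = {
        name: rng.random(n) < p
        for name, p in factor_p.items()
        if name not in coupled or name in {a for a, _ in config.pairwise_odds_ratios}
    }
    for (a, b), odds in config.pairwise_odds_ratios.items():
        if a not in factor_p or b not in factor_p:
            raise ConfigError(f"odds-ratio pair ({a}, {b}) names unknown factors")
        pa, pb = factor_p[a], factor_p[b]
        p11 = _joint_p11(pa, pb, odds)
        p_b_given_a = p11 / pa if pa > 0 else 0.0
        p_b_given_not_a = (pb - p11) / (1 - pa) if pa < 1 else 0.0
        u = rng.random(n)
        draws[b] = np.where(draws[a], u < p_b_given_a, u < p_b_given_not_a)

    # personal cancer history categories
    u = rng.random(n)
    p1 = config.p_breast_cancer_only
    p2 = p1 + config.p_ovarian_cancer_only
    p3 = p2 + config.p_breast_and_ovarian
    breast_ca = (u < p1) | ((u >= p2) & (u < p3))
    ovarian_ca = (u >= p1) & (u < p3)

    # genetic testing
    tested = rng.random(n) < config.p_personal_tested
    u = rng.random(n)
    high_pos = tested & (u < config.p_high_gene_given_tested)
    mod_pos = tested & ~high_pos & (
        u < config.p_high_gene_given_tested + config.p_moderate_gene_given_tested
    )
    high_panel = sorted(HIGH_PENETRANCE)
    mod_panel = sorted(MODERATE_LOWER)
    gene_pick = rng.integers(0, max(len(high_panel), len(mod_panel)), size=n)
    fam_tested = rng.random(n) < config.p_family_member_tested
    fam_pos = fam_tested & (rng.random(n) < config.p_family_positive_given_tested)

    fh_known = rng.random(n) < config.p_family_history_known

    # behaviors
    bmi = rng.normal(config.bmi_mean, config.bmi_sd, size=n)
    while np.any(bmi < config.bmi_min):  # truncated normal by resampling
        bad = bmi < config.bmi_min
        bmi[bad] = rng.normal(config.bmi_mean, config.bmi_sd, size=int(bad.sum()))
    ever_pregnant = rng.random(n) < config.p_ever_pregnant
    breastfed_draw = rng.random(n) < config.p_breastfed_given_pregnant

    cohort: list[Respondent] = []
    for i in range(n):
        race, aj, hisp = STRATUM_FIELDS[strata[stratum_idx[i]]]
        known = bool(fh_known[i])
        genes: frozenset[str] = frozenset()
        if high_pos[i]:
            genes = frozenset({high_panel[gene_pick[i] % len(high_panel)]})
        elif mod_pos[i]:
            genes = frozenset({mod_panel[gene_pick[i] % len(mod_panel)]})
        fh_kwargs = {
            flag: bool(draws[flag][i]) and known for flag in FH_FLAGS
        }
        cohort.append(
            Respondent(
                id=f"s{config.seed}-{i:06d}",
                age=int(ages[i]),
                race=race,
                ashkenazi_jewish=aj,
                hispanic_latina=hisp,
                personal_breast_cancer=bool(breast_ca[i]),
                personal_ovarian_cancer=bool(ovarian_ca[i]),
                personal_tested=bool(tested[i]),
                personal_positive_genes=genes,
                family_member_tested=bool(fam_tested[i]),
                family_member_positive=bool(fam_pos[i]),
                family_history_known=known,
                chest_radiation=bool(draws["chest_radiation"][i]),
                abnormal_biopsy=bool(draws["abnormal_biopsy"][i]),
                pcos=bool(draws["pcos"][i]),
                dense_breasts=bool(draws["dense_breasts"][i]),
                bmi=float(round(bmi[i], 1)),
                alcohol_ge2_per_day=bool(draws["alcohol_ge2_per_day"][i]),
                exercise_lt150_min=bool(draws["exercise_lt150_min"][i]),
                current_smoker=bool(draws["current_smoker"][i]),
                breastfed=bool(breastfed_draw[i]) if ever_pregnant[i] else None,
                **fh_kwargs,
            )
        )
    return cohort


def _blank(rid: str, age: int, stratum: str) -> Respondent:
    race, aj, hisp = STRATUM_FIELDS[stratum]
    return Respondent(
        id=rid,
        age=age,
        race=race,
        ashkenazi_jewish=aj,
        hispanic_latina=hisp,
        family_history_known=True,
    )


# cycled across false-positive cells so all three AYR-only factors appear
_EXTRA_TRIGGERS = ("pcos", "chest_radiation", "abnormal_biopsy")


def generate_confusion_cohort(
    tp: int,
    fp: int,
    fn: int,
    tn: int,
    mode: str = "nccn",
    seed: int = 0,
    stratum: str = "white",
    age: int = 25,
    id_prefix: str = "",
) -> list[Respondent]:
    """Build a cohort whose AYR-vs-reference confusion matrix is exactly
    (tp, fp, fn, tn).

    ``mode`` selects the reference classifier the matrix targets.  True
    positives carry one family-history trigger (rotated pseudo-randomly);
    true negatives are trigger-free.  False positives are respondents whose
    only trigger is one of the AYR-only factors (mode ``nccn``) or a
    personal high-penetrance gene (mode ``nccn_plus_extras`` — the only
    factor the augmented reference still ignores; such fixtures are meant
    for exclusion-free use, since a high-penetrance positive would otherwise
    be excluded).  False negatives are unrealizable: every reference-eligible
    respondent fires an AYR rule by construction of the rule sets.

    ``stratum`` and ``age`` set the demographics of every generated
    respondent, so stratified tables can be assembled block by block.
    """
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0:
            raise UnrealizableFixtureError(f"{name} must be non-negative, got {v}")
    if mode not in ("nccn", "nccn_plus_extras"):
        raise UnrealizableFixtureError(f"unknown reference mode {mode!r}")
    if fn > 0:
        raise UnrealizableFixtureError(
            "fn > 0 is unrealizable: every reference-eligible respondent "
            "fires an AYR increased/high rule (superset property)"
        )
    if stratum not in STRATUM_FIELDS:
        raise UnrealizableFixtureError(f"unknown stratum {stratum!r}")

    rng = np.random.default_rng(seed)
    fh_choice = rng.integers(0, len(FH_FLAGS), size=tp)
    cohort: list[Respondent] = []
    for i in range(tp):
        r = _blank(f"{id_prefix}tp-{i:06d}", age, stratum)
        setattr(r, FH_FLAGS[fh_choice[i]], True)
        cohort.append(r)
    for i in range(fp):
        r = _blank(f"{id_prefix}fp-{i:06d}", age, stratum)
        if mode == "nccn":
            setattr(r, _EXTRA_TRIGGERS[i % len(_EXTRA_TRIGGERS)], True)
        else:
            r.personal_tested = True
            r.personal_positive_genes = frozenset({"BRCA1"})
        cohort.append(r)
    for i in range(tn):
        cohort.append(_blank(f"{id_prefix}tn-{i:06d}", age, stratum))
    return cohort


def generate_excluded_block(
    n_high_by_testing: int,
    n_personal_cancer: int,
    n_unknown_family_history: int,
    n_union: int,
    seed: int = 0,
    stratum: str = "white",
    age: int = 25,
    id_prefix: str = "x",
) -> list[Respondent]:
    """Build ``n_union`` respondents realizing a target exclusion structure.

    The three per-rule counts may overlap; the required overlap
    (sum of counts minus union) is allocated greedily to the pairwise
    intersections cancer∩unknown-history, high∩unknown-history, high∩cancer.
    Raises :class:`UnrealizableFixtureError` when no allocation exists.
    """
    a, b, c, u = n_high_by_testing, n_personal_cancer, n_unknown_family_history, n_union
    if min(a, b, c, u) < 0:
        raise UnrealizableFixtureError("counts must be non-negative")
    overlap = a + b + c - u
    if overlap < 0:
        raise UnrealizableFixtureError(
            f"union {u} exceeds the sum of the per-rule counts {a + b + c}"
        )
    bc = min(overlap, b, c)
    ac = min(overlap - bc, a, c - bc)
    ab = min(overlap - bc - ac, a - ac, b - bc)
    if ab + ac + bc != overlap:
        raise UnrealizableFixtureError(
            f"overlap of {overlap} cannot be packed into pairwise intersections "
            f"of counts ({a}, {b}, {c})"
        )

    def make(i: int, high: bool, cancer: bool, unknown: bool) -> Respondent:
        r = _blank(f"{id_prefix}-{i:06d}", age, stratum)
        if high:
            r.personal_tested = True
            r.personal_positive_genes = frozenset({"BRCA1"})
        if cancer:
            r.personal_breast_cancer = True
        if unknown:
            r.family_history_known = False
        return r

    cells = [
        (a - ab - ac, True, False, False),
        (b - ab - bc, False, True, False),
        (c - ac - bc, False, False, True),
        (ab, True, True, False),
        (ac, True, False, True),
        (bc, False, True, True),
    ]
    cohort: list[Respondent] = []
    i = 0
    for count, high, cancer, unknown in cells:
        for _ in range(count):
            cohort.append(make(i, high, cancer, unknown))
            i += 1
    return cohort
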