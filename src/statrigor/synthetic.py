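"""Synthetic audit-corpus generator.

Emulates a corpus of appraised clinical articles whose categorical marginals
match the published descriptive summary of the audited prosthodontic
literature (n = 119, 2019-2024), together with the two structural couplings
the audit reports:

* statistician involvement forces appropriate test selection (every
  statistician-involved study in the audit matched tests to variables); and
* the error classification is *derived* by scoring each generated record,
  never sampled, so the strong Domain-1/Domain-3 associations with the
  outcome arise structurally.

Fields are otherwise sampled independently given the structural constraints
(conditional tables keep normality/homogeneity statuses consistent with
whether the primary test is parametric, and calibration quality consistent
with calibration being mentioned).  All draws go through a single seeded
generator, so corpora are bit-reproducible.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .articles import (
    ArticleRecord,
    AssumptionsRequired,
    CalibrationQuality,
    CIStatus,
    ConditionalAssumptionStatus,
    Continent,
    GroupsClass,
    IndependenceStatus,
    Journal,
    NonsigDiscussion,
    TestPattern,
    TestVariableMatch,
    VariableType,
)
from .scoring import ScoreCard, Weights, DEFAULT_WEIGHTS, score_corpus

__all__ = ["CorpusConfig", "default_config", "generate_corpus", "classify_corpus"]

_N_REF = 119  # published corpus size the default marginals are calibrated to

_PROB_SUM_TOL = 1e-9


def _probs(counts: dict[str, int], total: int) -> dict[str, float]:
    return {k: v / total for k, v in counts.items()}


class CorpusConfig(BaseModel):
    """Marginal probabilities, coupling switches, corpus size and seed.

    Defaults reproduce the published audit's category frequencies out of
    119 articles (e.g. 105/119 appropriate test-variable matches, 19/119
    with statistician involvement, independence violated/maintained/unclear
    = 30/78/11).
    """

    model_config = ConfigDict(extra="forbid")

    n_articles: int = Field(default=_N_REF, ge=0)
    seed: int = 0

    journal_probs: dict[str, float] = Field(
        default_factory=lambda: _probs({"jop": 25, "ijop": 37, "jpd": 57}, _N_REF)
    )
    year_probs: dict[int, float] = Field(
        default_factory=lambda: _probs(
            {2019: 22, 2020: 14, 2021: 18, 2022: 24, 2023: 22, 2024: 19}, _N_REF
        )
    )
    continent_probs: dict[str, float] = Field(
        default_factory=lambda: _probs(
            {
                "asia": 46,
                "europe": 38,
                "north_america": 18,
                "south_america": 13,
                "africa": 3,
                "australia": 1,
            },
            _N_REF,
        )
    )
    dependent_var_probs: dict[str, float] = Field(
        default_factory=lambda: _probs(
            {"continuous": 43, "categorical": 19, "ordinal": 11, "mixed": 46}, _N_REF
        )
    )
    independent_var_probs: dict[str, float] = Field(
        default_factory=lambda: _probs(
            {"continuous": 2, "categorical": 105, "ordinal": 1, "mixed": 11}, _N_REF
        )
    )
    n_groups_probs: dict[str, float] = Field(
        default_factory=lambda: _probs({"lt3": 55, "ge3": 64}, _N_REF)
    )
    test_pattern_probs: dict[str, float] = Field(
        default_factory=lambda: _probs({"single": 24, "multiple": 95}, _N_REF)
    )

    p_statistician: float = Field(default=19 / _N_REF, ge=0.0, le=1.0)
    p_match_given_statistician: float = Field(default=1.0, ge=0.0, le=1.0)
    p_match_given_no_statistician: float = Field(default=86 / 100, ge=0.0, le=1.0)

    p_sample_size_reported: float = Field(default=38 / _N_REF, ge=0.0, le=1.0)

    # Domain 3: 57/119 articles used parametric tests (normality/homogeneity
    # required); the rest require independence only.
    p_parametric_required: float = Field(default=57 / _N_REF, ge=0.0, le=1.0)
    independence_probs: dict[str, float] = Field(
        default_factory=lambda: _probs(
            {"violated": 30, "maintained": 78, "unclear": 11}, _N_REF
        )
    )
    normality_given_parametric: dict[str, float] = Field(
        default_factory=lambda: _probs(
            {"required_not_tested": 38, "required_tested_satisfied": 19}, 57
        )
    )
    normality_given_nonparametric: dict[str, float] = Field(
        default_factory=lambda: _probs(
            {"not_required_tested": 17, "not_required_not_tested": 45}, 62
        )
    )
    homogeneity_given_parametric: dict[str, float] = Field(
        default_factory=lambda: _probs(
            {"required_not_tested": 49, "required_tested_satisfied": 8}, 57
        )
    )
    homogeneity_given_nonparametric: dict[str, float] = Field(
        default_factory=lambda: _probs(
            {"not_required_tested": 1, "not_required_not_tested": 61}, 62
        )
    )

    p_calibration_mentioned: float = Field(default=48 / _N_REF, ge=0.0, le=1.0)
    p_calibration_appropriate_given_mentioned: float = Field(
        default=33 / 48, ge=0.0, le=1.0
    )

    # Domain 5 items; p-values were reported universally in the audit.
    p_p_values_reported: float = Field(default=1.0, ge=0.0, le=1.0)
    ci_probs: dict[str, float] = Field(
        default_factory=lambda: _probs(
            {"not_reported": 99, "reported_not_interpreted": 11, "reported_interpreted": 9},
            _N_REF,
        )
    )
    p_nonsig_full: float = Field(default=60 / _N_REF, ge=0.0, le=1.0)
    p_limitations_discussed: float = Field(default=116 / _N_REF, ge=0.0, le=1.0)
    p_assumption_violations_reported: float = Field(default=42 / _N_REF, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check_probability_vectors(self) -> "CorpusConfig":
        vectors = {
            "journal_probs": (self.journal_probs, {j.value for j in Journal}),
            "year_probs": (self.year_probs, set(range(2019, 2025))),
            "continent_probs": (self.continent_probs, {c.value for c in Continent}),
            "dependent_var_probs": (self.dependent_var_probs, {v.value for v in VariableType}),
            "independent_var_probs": (self.independent_var_probs, {v.value for v in VariableType}),
            "n_groups_probs": (self.n_groups_probs, {g.value for g in GroupsClass}),
            "test_pattern_probs": (self.test_pattern_probs, {t.value for t in TestPattern}),
            "independence_probs": (self.independence_probs, {s.value for s in IndependenceStatus}),
            "normality_given_parametric": (
                self.normality_given_parametric,
                {"required_not_tested", "required_tested_satisfied"},
            ),
            "normality_given_nonparametric": (
                self.normality_given_nonparametric,
                {"not_required_tested", "not_required_not_tested"},
            ),
            "homogeneity_given_parametric": (
                self.homogeneity_given_parametric,
                {"required_not_tested", "required_tested_satisfied"},
            ),
            "homogeneity_given_nonparametric": (
                self.homogeneity_given_nonparametric,
                {"not_required_tested", "not_required_not_tested"},
            ),
            "ci_probs": (self.ci_probs, {s.value for s in CIStatus}),
        }
        for name, (vec, allowed) in vectors.items():
            bad = set(vec) - allowed
            if bad:
                raise ValueError(f"{name}: unknown categories {sorted(map(str, bad))}")
            if any(p < 0 or p > 1 for p in vec.values()):
                raise ValueError(f"{name}: probabilities must lie in [0, 1]")
            if abs(sum(vec.values()) - 1.0) > _PROB_SUM_TOL:
                raise ValueError(
                    f"{name}: probabilities sum to {sum(vec.values())!r}, expected 1"
                )
        return self


def default_config(seed: int = 0, n_articles: int = _N_REF) -> CorpusConfig:
    """Config whose marginals equal the published descriptive frequencies."""
    return CorpusConfig(seed=seed, n_articles=n_articles)


def _draw_categorical(rng: np.random.Generator, probs: dict, size: int) -> np.ndarray:
    keys = np.array(list(probs.keys()), dtype=object)
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()  # renormalize away float round-off within tolerance
    return keys[rng.choice(len(keys), size=size, p=p)]


def generate_corpus(config: CorpusConfig) -> list[ArticleRecord]:
    """Generate ``config.n_articles`` structurally valid records.

    Deterministic for a fixed config and seed; all randomness flows through
    one ``numpy`` generator seeded with ``config.seed``.
    """
    n = config.n_articles
    rng = np.random.default_rng(config.seed)
    if n == 0:
        return []

    journal = _draw_categorical(rng, config.journal_probs, n)
    year = _draw_categorical(rng, config.year_probs, n)
    statistician = rng.random(n) < config.p_statistician
    continent = _draw_categorical(rng, config.continent_probs, n)
    dep_var = _draw_categorical(rng, config.dependent_var_probs, n)
    ind_var = _draw_categorical(rng, config.independent_var_probs, n)
    n_groups = _draw_categorical(rng, config.n_groups_probs, n)
    pattern = _draw_categorical(rng, config.test_pattern_probs, n)

    p_match = np.where(
        statistician,
        config.p_match_given_statistician,
        config.p_match_given_no_statistician,
    )
    match = rng.random(n) < p_match

    sample_size = rng.random(n) < config.p_sample_size_reported

    parametric = rng.random(n) < config.p_parametric_required
    independence = _draw_categorical(rng, config.independence_probs, n)

    normality = np.empty(n, dtype=object)
    homogeneity = np.empty(n, dtype=object)
    n_param = int(parametric.sum())
    n_nonparam = n - n_param
    if n_param:
        normality[parametric] = _draw_categorical(
            rng, config.normality_given_parametric, n_param
        )
        homogeneity[parametric] = _draw_categorical(
            rng, config.homogeneity_given_parametric, n_param
        )
    if n_nonparam:
        normality[~parametric] = _draw_categorical(
            rng, config.normality_given_nonparametric, n_nonparam
        )
        homogeneity[~parametric] = _draw_categorical(
            rng, config.homogeneity_given_nonparametric, n_nonparam
        )

    calib_mentioned = rng.random(n) < config.p_calibration_mentioned
    calib_appropriate = rng.random(n) < config.p_calibration_appropriate_given_mentioned

    p_values = rng.random(n) < config.p_p_values_reported
    ci = _draw_categorical(rng, config.ci_probs, n)
    nonsig_full = rng.random(n) < config.p_nonsig_full
    limitations = rng.random(n) < config.p_limitations_discussed
    violations_reported = rng.random(n) < config.p_assumption_violations_reported

    width = max(4, len(str(n - 1)))
    records = []
    for i in range(n):
        if calib_mentioned[i]:
            quality = (
                CalibrationQuality.APPROPRIATE
                if calib_appropriate[i]
                else CalibrationQuality.INAPPROPRIATE
            )
        else:
            quality = CalibrationQuality.NOT_APPLICABLE
        records.append(
            ArticleRecord(
                article_id=f"A{i:0{width}d}",
                journal=Journal(journal[i]),
                year=int(year[i]),
                statistician_involved=bool(statistician[i]),
                continent=Continent(continent[i]),
                dependent_var_type=VariableType(dep_var[i]),
                independent_var_type=VariableType(ind_var[i]),
                n_groups_class=GroupsClass(n_groups[i]),
                test_pattern=TestPattern(pattern[i]),
                test_variable_match=(
                    TestVariableMatch.APPROPRIATE
                    if match[i]
                    else TestVariableMatch.INAPPROPRIATE
                ),
                sample_size_reported=bool(sample_size[i]),
                assumptions_required=(
                    AssumptionsRequired.INDEPENDENCE_NORMALITY_HOMOGENEITY
                    if parametric[i]
                    else AssumptionsRequired.INDEPENDENCE_ONLY
                ),
                independence_status=IndependenceStatus(independence[i]),
                normality_status=ConditionalAssumptionStatus(normality[i]),
                homogeneity_status=ConditionalAssumptionStatus(homogeneity[i]),
                calibration_mentioned=bool(calib_mentioned[i]),
                calibration_quality=quality,
                p_values_reported=bool(p_values[i]),
                ci_status=CIStatus(ci[i]),
                nonsig_discussion=(
                    NonsigDiscussion.FULL if nonsig_full[i] else NonsigDiscussion.BRIEF
                ),
                limitations_discussed=bool(limitations[i]),
                assumption_violations_reported=bool(violations_reported[i]),
            )
        )
    return records


def classify_corpus(
    records, weights: Weights = DEFAULT_WEIGHTS
) -> list[ScoreCard]:
    """Score a corpus; the classification is derived, never sampled."""
    return score_corpus(records, weights)
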