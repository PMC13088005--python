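"""Weighted checklist scoring and three-way error classification.

Five domains are scored per article:

1. appropriateness of statistical test selection (0/1, weight 0.35),
2. sample-size calculation and justification (0/1, weight 0.15),
3. statistical assumption testing (0/0.5/1, weight 0.35),
4. calibration and reliability (0/1, weight 0.05),
5. interpretation of results (0/0.5/1 from a five-item raw sum, weight 0.10).

The composite is the weighted sum in [0, 1], and each article is classified
as having *no major*, *minor*, or *major* statistical error:

* major   — Domain 1 or Domain 3 scored 0, or composite < 0.60;
* no major — composite >= 0.80, or Domains 1 and 3 both 1 with composite >= 0.70;
* minor   — everything else (partial deficiencies: a 0.5 domain score or a
  composite in [0.60, 0.80) not meeting the no-major criteria).

Major conditions take precedence, then no-major, then the minor residual.
Threshold comparisons carry a 1e-9 tolerance against floating-point noise
in the weighted sum.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence, Union

from .articles import (
    ArticleRecord,
    AssumptionsRequired,
    CalibrationQuality,
    CIStatus,
    ConditionalAssumptionStatus,
    IndependenceStatus,
    NonsigDiscussion,
    TestVariableMatch,
)

__all__ = [
    "Weights",
    "DEFAULT_WEIGHTS",
    "Classification",
    "ScoreCard",
    "score_domain1",
    "score_domain2",
    "score_domain3",
    "score_domain4",
    "score_domain5",
    "composite_score",
    "classify",
    "score_record",
    "score_corpus",
    "write_scorecards_csv",
    "write_scorecards_json",
]

#: Tolerance for comparisons against the classification thresholds.
TOL = 1e-9


class ConfigurationError(ValueError):
    """Invalid scoring configuration (e.g. weights not summing to one)."""


@dataclass(frozen=True)
class Weights:
    """Domain weights; must be nonnegative and sum to 1."""

    w1: float = 0.35
    w2: float = 0.15
    w3: float = 0.35
    w4: float = 0.05
    w5: float = 0.10

    def __post_init__(self):
        ws = (self.w1, self.w2, self.w3, self.w4, self.w5)
        if any(w < 0 for w in ws):
            raise ConfigurationError(f"weights must be nonnegative, got {ws}")
        if abs(sum(ws) - 1.0) > TOL:
            raise ConfigurationError(f"weights must sum to 1, got sum {sum(ws)!r}")


DEFAULT_WEIGHTS = Weights()


class Classification(str, enum.Enum):
    NO_MAJOR = "no_major"
    MINOR = "minor"
    MAJOR = "major"


@dataclass(frozen=True)
class ScoreCard:
    article_id: str
    d1: float
    d2: float
    d3: float
    d4: float
    d5_raw: float
    d5: float
    composite: float
    classification: Classification


def score_domain1(record: ArticleRecord) -> float:
    """Test appropriateness: 1 iff all tests matched the variable types."""
    return 1.0 if record.test_variable_match is TestVariableMatch.APPROPRIATE else 0.0


def score_domain2(record: ArticleRecord) -> float:
    """Sample-size justification: 1 iff a calculation was reported."""
    return 1.0 if record.sample_size_reported else 0.0


def score_domain3(record: ArticleRecord) -> float:
    """Assumption testing: 0 violated, 1 fully addressed, 0.5 partial.

    Independence violated scores 0 outright.  A full score requires
    independence maintained and — when the primary test is parametric —
    normality and homogeneity both tested and satisfied; for non-parametric
    tests the extra requirement is vacuous.  Anything in between (unclear
    independence, required checks missing) is partial.
    """
    if record.independence_status is IndependenceStatus.VIOLATED:
        return 0.0
    if record.independence_status is IndependenceStatus.MAINTAINED:
        if record.assumptions_required is AssumptionsRequired.INDEPENDENCE_ONLY:
            return 1.0
        sat = ConditionalAssumptionStatus.REQUIRED_TESTED_SATISFIED
        if record.normality_status is sat and record.homogeneity_status is sat:
            return 1.0
    return 0.5


def score_domain4(record: ArticleRecord) -> float:
    """Calibration/reliability: 1 iff mentioned and methodologically sound."""
    return (
        1.0
        if record.calibration_mentioned
        and record.calibration_quality is CalibrationQuality.APPROPRIATE
        else 0.0
    )


_CI_ITEM = {
    CIStatus.REPORTED_INTERPRETED: 1.0,
    CIStatus.REPORTED_NOT_INTERPRETED: 0.5,
    CIStatus.NOT_REPORTED: 0.0,
}


def score_domain5(record: ArticleRecord) -> tuple[float, float]:
    """Interpretation of results: (raw item sum in [0, 5], category score).

    Items: p-values reported (1), confidence intervals (1 interpreted /
    0.5 reported only / 0 absent), non-significant results discussed
    (1 fully / 0.5 briefly), limitations discussed (1), assumption
    violations acknowledged (1).  Raw >= 3 is fully met (1), 2 <= raw < 3
    partially met (0.5), raw < 2 not met (0).
    """
    raw = (
        (1.0 if record.p_values_reported else 0.0)
        + _CI_ITEM[record.ci_status]
        + (1.0 if record.nonsig_discussion is NonsigDiscussion.FULL else 0.5)
        + (1.0 if record.limitations_discussed else 0.0)
        + (1.0 if record.assumption_violations_reported else 0.0)
    )
    if raw >= 3.0 - TOL:
        score = 1.0
    elif raw >= 2.0 - TOL:
        score = 0.5
    else:
        score = 0.0
    return raw, score


def composite_score(
    d1: float,
    d2: float,
    d3: float,
    d4: float,
    d5: float,
    weights: Weights = DEFAULT_WEIGHTS,
) -> float:
    """Weighted composite of the five domain scores."""
    return (
        weights.w1 * d1
        + weights.w2 * d2
        + weights.w3 * d3
        + weights.w4 * d4
        + weights.w5 * d5
    )


def classify(d1: float, d3: float, composite: float) -> Classification:
    """Map (Domain 1, Domain 3, composite) to the error classification."""
    if d1 not in (0.0, 1.0):
        raise ValueError(f"d1 must be 0 or 1, got {d1!r}")
    if d3 not in (0.0, 0.5, 1.0):
        raise ValueError(f"d3 must be 0, 0.5 or 1, got {d3!r}")
    if not (-TOL <= composite <= 1.0 + TOL):
        raise ValueError(f"composite must lie in [0, 1], got {composite!r}")
    if d1 == 0.0 or d3 == 0.0 or composite < 0.60 - TOL:
        return Classification.MAJOR
    if composite >= 0.80 - TOL or (d1 == 1.0 and d3 == 1.0 and composite >= 0.70 - TOL):
        return Classification.NO_MAJOR
    return Classification.MINOR


def score_record(
    record: ArticleRecord, weights: Weights = DEFAULT_WEIGHTS
) -> ScoreCard:
    d1 = score_domain1(record)
    d2 = score_domain2(record)
    d3 = score_domain3(record)
    d4 = score_domain4(record)
    d5_raw, d5 = score_domain5(record)
    comp = composite_score(d1, d2, d3, d4, d5, weights)
    return ScoreCard(
        article_id=record.article_id,
        d1=d1,
        d2=d2,
        d3=d3,
        d4=d4,
        d5_raw=d5_raw,
        d5=d5,
        composite=comp,
        classification=classify(d1, d3, comp),
    )


def score_corpus(
    records: Iterable[ArticleRecord], weights: Weights = DEFAULT_WEIGHTS
) -> list[ScoreCard]:
    """Score every record, preserving order and ids."""
    return [score_record(rec, weights) for rec in records]


_SCORECARD_COLUMNS = (
    "article_id",
    "d1",
    "d2",
    "d3",
    "d4",
    "d5_raw",
    "d5",
    "composite",
    "classification",
)


def write_scorecards_csv(cards: Sequence[ScoreCard], path: Union[str, Path]) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SCORECARD_COLUMNS)
        for c in cards:
            writer.writerow(
                [
                    c.article_id,
                    c.d1,
                    c.d2,
                    c.d3,
                    c.d4,
                    c.d5_raw,
                    c.d5,
                    c.composite,
                    c.classification.value,
                ]
            )
    return path


def write_scorecards_json(cards: Sequence[ScoreCard], path: Union[str, Path]) -> Path:
    path = Path(path)
    payload = [
        {**asdict(c), "classification": c.classification.value} for c in cards
    ]
    path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
    return path
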