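"""Shared fixtures: record builders, a marginal-exact 119-article corpus,
and a hypothesis strategy for structurally valid article records."""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import strategies as st

from statrigor.articles import (
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


def make_record(**overrides) -> ArticleRecord:
    """A structurally valid baseline record; override any field."""
    base = dict(
        article_id="A0001",
        journal=Journal.JPD,
        year=2022,
        statistician_involved=False,
        continent=Continent.ASIA,
        dependent_var_type=VariableType.CONTINUOUS,
        independent_var_type=VariableType.CATEGORICAL,
        n_groups_class=GroupsClass.LT3,
        test_pattern=TestPattern.MULTIPLE,
        test_variable_match=TestVariableMatch.APPROPRIATE,
        sample_size_reported=True,
        assumptions_required=AssumptionsRequired.INDEPENDENCE_ONLY,
        independence_status=IndependenceStatus.MAINTAINED,
        normality_status=ConditionalAssumptionStatus.NOT_REQUIRED_NOT_TESTED,
        homogeneity_status=ConditionalAssumptionStatus.NOT_REQUIRED_NOT_TESTED,
        calibration_mentioned=True,
        calibration_quality=CalibrationQuality.APPROPRIATE,
        p_values_reported=True,
        ci_status=CIStatus.REPORTED_INTERPRETED,
        nonsig_discussion=NonsigDiscussion.FULL,
        limitations_discussed=True,
        assumption_violations_reported=True,
    )
    base.update(overrides)
    return ArticleRecord(**base)


@pytest.fixture
def best_record() -> ArticleRecord:
    """Every domain at its ceiling: composite 1.0, no major error."""
    return make_record()


def marginal_exact_corpus() -> list[ArticleRecord]:
    """A 119-article corpus hitting the audited marginals exactly.

    By construction: 105 appropriate test-variable matches, 38 sample-size
    reports, 56 articles with all assumptions met (Domain 3 = 1), 30 with
    independence violated (Domain 3 = 0), 33 unclear (Domain 3 = 0.5),
    confidence intervals 99 absent / 11 uninterpreted / 9 interpreted, and
    derived outcome counts 53 no-major / 41 major / 25 minor.
    """
    records = []
    for i in range(119):
        # Domain 3 block: 0-55 all met, 56-85 violated, 86-118 unclear.
        if i < 56:
            independence = IndependenceStatus.MAINTAINED
        elif i < 86:
            independence = IndependenceStatus.VIOLATED
        else:
            independence = IndependenceStatus.UNCLEAR
        # 14 inappropriate matches: 3 in the all-met block, 3 overlapping the
        # violated block, 8 in the unclear block.
        inappropriate = i in range(0, 3) or i in range(56, 59) or i in range(86, 94)
        # 38 sample-size reports: the 25 minor-error articles (94-118) plus 13.
        sample_size = i < 13 or i >= 94
        if i < 9:
            ci = CIStatus.REPORTED_INTERPRETED
        elif i < 20:
            ci = CIStatus.REPORTED_NOT_INTERPRETED
        else:
            ci = CIStatus.NOT_REPORTED
        records.append(
            make_record(
                article_id=f"A{i:04d}",
                independence_status=independence,
                test_variable_match=(
                    TestVariableMatch.INAPPROPRIATE
                    if inappropriate
                    else TestVariableMatch.APPROPRIATE
                ),
                sample_size_reported=sample_size,
                ci_status=ci,
                calibration_mentioned=False,
                calibration_quality=CalibrationQuality.NOT_APPLICABLE,
                nonsig_discussion=NonsigDiscussion.BRIEF,
                assumption_violations_reported=False,
            )
        )
    return records


@pytest.fixture(scope="session")
def exact_corpus() -> list[ArticleRecord]:
    return marginal_exact_corpus()


@st.composite
def article_records(draw, article_id: str = "H0001") -> ArticleRecord:
    """Structurally valid random records (invariants hold by construction)."""
    assumptions = draw(st.sampled_from(list(AssumptionsRequired)))
    if assumptions is AssumptionsRequired.INDEPENDENCE_ONLY:
        cond = st.sampled_from(
            [
                ConditionalAssumptionStatus.NOT_REQUIRED_TESTED,
                ConditionalAssumptionStatus.NOT_REQUIRED_NOT_TESTED,
            ]
        )
    else:
        cond = st.sampled_from(
            [
                ConditionalAssumptionStatus.REQUIRED_NOT_TESTED,
                ConditionalAssumptionStatus.REQUIRED_TESTED_SATISFIED,
            ]
        )
    calibration_mentioned = draw(st.booleans())
    quality = (
        draw(
            st.sampled_from(
                [CalibrationQuality.APPROPRIATE, CalibrationQuality.INAPPROPRIATE]
            )
        )
        if calibration_mentioned
        else CalibrationQuality.NOT_APPLICABLE
    )
    return make_record(
        article_id=article_id,
        journal=draw(st.sampled_from(list(Journal))),
        year=draw(st.integers(2019, 2024)),
        statistician_involved=draw(st.booleans()),
        continent=draw(st.sampled_from(list(Continent))),
        dependent_var_type=draw(st.sampled_from(list(VariableType))),
        independent_var_type=draw(st.sampled_from(list(VariableType))),
        n_groups_class=draw(st.sampled_from(list(GroupsClass))),
        test_pattern=draw(st.sampled_from(list(TestPattern))),
        test_variable_match=draw(st.sampled_from(list(TestVariableMatch))),
        sample_size_reported=draw(st.booleans()),
        assumptions_required=assumptions,
        independence_status=draw(st.sampled_from(list(IndependenceStatus))),
        normality_status=draw(cond),
        homogeneity_status=draw(cond),
        calibration_mentioned=calibration_mentioned,
        calibration_quality=quality,
        p_values_reported=draw(st.booleans()),
        ci_status=draw(st.sampled_from(list(CIStatus))),
        nonsig_discussion=draw(st.sampled_from(list(NonsigDiscussion))),
        limitations_discussed=draw(st.booleans()),
        assumption_violations_reported=draw(st.booleans()),
    )


@st.composite
def article_corpora(draw, min_size: int = 0, max_size: int = 20):
    n = draw(st.integers(min_size, max_size))
    return [
        dataclasses.replace(draw(article_records()), article_id=f"H{i:04d}")
        for i in range(n)
    ]
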