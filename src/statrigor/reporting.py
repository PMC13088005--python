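"""Descriptive summaries, error decomposition, association table, pipeline.

Produces the audit's three report products as plain data tables:

* a descriptive frequency/percentage summary of every coded article
  characteristic plus the derived domain statuses and the overall error
  classification (percentages to one decimal, half-up);
* the decomposition of major-error articles by failing domain (test
  selection only, assumption handling only, both, or composite-only);
* the association table crossing article characteristics and domain scores
  with the three-level outcome: Pearson chi-square with a Monte Carlo exact
  p-value when the expected counts are sparse, Cramér's V with a percentile
  bootstrap CI, and Cohen's effect-size label.

``run_pipeline`` chains simulate -> score -> summarize -> associate and
writes everything (plus a run manifest) under an output directory.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

from .articles import ArticleRecord, read_articles, write_articles
from .association import (
    AssociationResult,
    ContingencyTable,
    bootstrap_ci_cramers_v,
    chisq_independence,
    cramers_v,
    effect_size_label,
    monte_carlo_pvalue,
    needs_monte_carlo,
)
from .scoring import (
    Classification,
    ScoreCard,
    Weights,
    DEFAULT_WEIGHTS,
    score_corpus,
    write_scorecards_csv,
    write_scorecards_json,
)
from .synthetic import CorpusConfig, default_config, generate_corpus

__all__ = [
    "FrequencyTable",
    "ErrorDecomposition",
    "FactorAssociation",
    "percentage",
    "summarize_descriptives",
    "error_decomposition",
    "association_table",
    "run_pipeline",
    "DEFAULT_FACTORS",
]

logger = logging.getLogger("statrigor")


def percentage(count: int, n: int) -> float:
    """Percentage 100*count/n rounded half-up to one decimal."""
    if n <= 0:
        raise ValueError("n must be positive")
    exact = Decimal(count) * 100 / Decimal(n)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FrequencyTable:
    """Counts and one-decimal percentages of one categorical variable."""

    variable: str
    labels: tuple[str, ...]
    counts: tuple[int, ...]
    n: int
    percentages: tuple[float, ...]

    @classmethod
    def from_counts(
        cls, variable: str, labels: Sequence[str], counts: Sequence[int]
    ) -> "FrequencyTable":
        n = int(sum(counts))
        if n <= 0:
            raise ValueError(f"{variable}: counts sum to zero")
        return cls(
            variable=variable,
            labels=tuple(str(l) for l in labels),
            counts=tuple(int(c) for c in counts),
            n=n,
            percentages=tuple(percentage(c, n) for c in counts),
        )


def _count_by(values: Sequence[str], labels: Sequence[str]) -> list[int]:
    return [sum(1 for v in values if v == lab) for lab in labels]


_D3_STATUS = {0.0: "not_met", 0.5: "partially_met", 1.0: "all_met"}
_D5_STATUS = {0.0: "not_met", 0.5: "partially_met", 1.0: "fully_met"}


def _record_variables() -> list[tuple[str, Sequence[str], Callable[[ArticleRecord], str]]]:
    bool_labels = ("false", "true")
    return [
        ("journal", ("jop", "ijop", "jpd"), lambda r: r.journal.value),
        ("year", tuple(str(y) for y in range(2019, 2025)), lambda r: str(r.year)),
        ("statistician_involved", bool_labels, lambda r: str(r.statistician_involved).lower()),
        (
            "continent",
            ("asia", "europe", "north_america", "south_america", "africa", "australia"),
            lambda r: r.continent.value,
        ),
        (
            "dependent_var_type",
            ("continuous", "categorical", "ordinal", "mixed"),
            lambda r: r.dependent_var_type.value,
        ),
        (
            "independent_var_type",
            ("continuous", "categorical", "ordinal", "mixed"),
            lambda r: r.independent_var_type.value,
        ),
        ("n_groups_class", ("lt3", "ge3"), lambda r: r.n_groups_class.value),
        ("test_pattern", ("single", "multiple"), lambda r: r.test_pattern.value),
        (
            "test_variable_match",
            ("inappropriate", "appropriate"),
            lambda r: r.test_variable_match.value,
        ),
        ("sample_size_reported", bool_labels, lambda r: str(r.sample_size_reported).lower()),
        (
            "assumptions_required",
            ("independence_only", "independence_normality_homogeneity"),
            lambda r: r.assumptions_required.value,
        ),
        (
            "independence_status",
            ("violated", "maintained", "unclear"),
            lambda r: r.independence_status.value,
        ),
        (
            "normality_status",
            (
                "not_required_tested",
                "not_required_not_tested",
                "required_not_tested",
                "required_tested_satisfied",
            ),
            lambda r: r.normality_status.value,
        ),
        (
            "homogeneity_status",
            (
                "not_required_tested",
                "not_required_not_tested",
                "required_not_tested",
                "required_tested_satisfied",
            ),
            lambda r: r.homogeneity_status.value,
        ),
        ("calibration_mentioned", bool_labels, lambda r: str(r.calibration_mentioned).lower()),
        ("p_values_reported", bool_labels, lambda r: str(r.p_values_reported).lower()),
        (
            "ci_status",
            ("not_reported", "reported_not_interpreted", "reported_interpreted"),
            lambda r: r.ci_status.value,
        ),
        ("nonsig_discussion", ("brief", "full"), lambda r: r.nonsig_discussion.value),
        ("limitations_discussed", bool_labels, lambda r: str(r.limitations_discussed).lower()),
        (
            "assumption_violations_reported",
            bool_labels,
            lambda r: str(r.assumption_violations_reported).lower(),
        ),
    ]


def summarize_descriptives(
    records: Sequence[ArticleRecord], scorecards: Sequence[ScoreCard]
) -> list[FrequencyTable]:
    """One frequency table per coded variable, plus derived statuses and
    the outcome distribution.

    Calibration quality is tabulated over its applicable subset (articles
    that mention calibration), matching how the audit reports it.
    """
    if [r.article_id for r in records] != [c.article_id for c in scorecards]:
        raise ValueError("records and scorecards must be id-matched, in order")
    tables: list[FrequencyTable] = []
    for variable, labels, getter in _record_variables():
        values = [getter(r) for r in records]
        tables.append(
            FrequencyTable.from_counts(variable, labels, _count_by(values, labels))
        )
        if variable == "calibration_mentioned":
            mentioned = [r for r in records if r.calibration_mentioned]
            if mentioned:
                q_labels = ("appropriate", "inappropriate")
                q_values = [r.calibration_quality.value for r in mentioned]
                tables.append(
                    FrequencyTable.from_counts(
                        "calibration_quality", q_labels, _count_by(q_values, q_labels)
                    )
                )
    # Derived statuses from the scorecards.
    d3_labels = ("not_met", "all_met", "partially_met")
    d3_values = [_D3_STATUS[c.d3] for c in scorecards]
    tables.append(
        FrequencyTable.from_counts(
            "assumption_testing_overall", d3_labels, _count_by(d3_values, d3_labels)
        )
    )
    d5_labels = ("not_met", "fully_met", "partially_met")
    d5_values = [_D5_STATUS[c.d5] for c in scorecards]
    tables.append(
        FrequencyTable.from_counts(
            "domain5_overall", d5_labels, _count_by(d5_values, d5_labels)
        )
    )
    out_labels = ("no_major", "minor", "major")
    out_values = [c.classification.value for c in scorecards]
    tables.append(
        FrequencyTable.from_counts("outcome", out_labels, _count_by(out_values, out_labels))
    )
    return tables


@dataclass(frozen=True)
class ErrorDecomposition:
    """Partition of major-error articles by which critical domain failed."""

    n_major: int
    d1_only: int        # test selection failed, assumption handling did not
    d3_only: int        # assumption handling failed, test selection did not
    both: int           # both critical domains failed
    composite_only: int  # neither failed but the composite fell below 0.60
    pct_d1_only: float
    pct_d3_only: float
    pct_both: float
    pct_composite_only: float


def error_decomposition(scorecards: Sequence[ScoreCard]) -> ErrorDecomposition:
    majors = [c for c in scorecards if c.classification is Classification.MAJOR]
    n = len(majors)
    d1_only = sum(1 for c in majors if c.d1 == 0 and c.d3 > 0)
    d3_only = sum(1 for c in majors if c.d1 == 1 and c.d3 == 0)
    both = sum(1 for c in majors if c.d1 == 0 and c.d3 == 0)
    composite_only = n - d1_only - d3_only - both
    if n == 0:
        pcts = (0.0, 0.0, 0.0, 0.0)
    else:
        pcts = tuple(percentage(k, n) for k in (d1_only, d3_only, both, composite_only))
    return ErrorDecomposition(
        n_major=n,
        d1_only=d1_only,
        d3_only=d3_only,
        both=both,
        composite_only=composite_only,
        pct_d1_only=pcts[0],
        pct_d3_only=pcts[1],
        pct_both=pcts[2],
        pct_composite_only=pcts[3],
    )


DEFAULT_FACTORS = (
    "journal",
    "year",
    "statistician",
    "continent",
    "domain1",
    "domain2",
    "domain3",
    "domain4",
    "domain5",
)

_FACTOR_GETTERS: dict[str, Callable[[ArticleRecord, ScoreCard], str]] = {
    "journal": lambda r, c: r.journal.value,
    "year": lambda r, c: str(r.year),
    "statistician": lambda r, c: str(r.statistician_involved).lower(),
    "continent": lambda r, c: r.continent.value,
    "domain1": lambda r, c: str(c.d1),
    "domain2": lambda r, c: str(c.d2),
    "domain3": lambda r, c: str(c.d3),
    "domain4": lambda r, c: str(c.d4),
    "domain5": lambda r, c: str(c.d5),
}


@dataclass(frozen=True)
class FactorAssociation:
    """One association-table row: a factor crossed with the outcome."""

    factor: str
    computable: bool
    result: Optional[AssociationResult] = None
    mc_used: bool = False
    significant: Optional[bool] = None
    note: str = ""


def association_table(
    records: Sequence[ArticleRecord],
    scorecards: Sequence[ScoreCard],
    factors: Sequence[str] = DEFAULT_FACTORS,
    mc_replicates: int = 10_000,
    bootstrap_replicates: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[FactorAssociation]:
    """Cross each factor with the error classification and test association.

    The reported p-value is the Monte Carlo exact p whenever more than 20%
    of expected cell counts fall below 5, otherwise the asymptotic p; the
    significance flag always follows the reported p.
    """
    if [r.article_id for r in records] != [c.article_id for c in scorecards]:
        raise ValueError("records and scorecards must be id-matched, in order")
    unknown = [f for f in factors if f not in _FACTOR_GETTERS]
    if unknown:
        raise ValueError(f"unknown factor(s): {unknown}")
    outcome = [c.classification.value for c in scorecards]
    rows: list[FactorAssociation] = []
    for i, factor in enumerate(factors):
        getter = _FACTOR_GETTERS[factor]
        values = [getter(r, c) for r, c in zip(records, scorecards)]
        if len(set(values)) < 2 or len(set(outcome)) < 2:
            rows.append(
                FactorAssociation(
                    factor=factor,
                    computable=False,
                    note="factor or outcome has a single observed level",
                )
            )
            continue
        table = ContingencyTable.from_pairs(values, outcome)
        result = chisq_independence(table)
        mc_used = needs_monte_carlo(table)
        if mc_used:
            result.p_monte_carlo = monte_carlo_pvalue(
                table, replicates=mc_replicates, seed=seed + 1000 * i
            )
            result.mc_replicates = mc_replicates
        v = cramers_v(table)
        lo, hi = bootstrap_ci_cramers_v(
            values, outcome, replicates=bootstrap_replicates, seed=seed + 1000 * i + 1
        )
        result.cramers_v = v
        result.v_ci_low = lo
        result.v_ci_high = hi
        result.effect_label = effect_size_label(v)
        rows.append(
            FactorAssociation(
                factor=factor,
                computable=True,
                result=result,
                mc_used=mc_used,
                significant=result.p_value < alpha,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Pipeline plumbing


def _write_descriptives_csv(tables: Sequence[FrequencyTable], path: Path) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["variable", "category", "count", "n", "percentage"])
        for t in tables:
            for lab, cnt, pct in zip(t.labels, t.counts, t.percentages):
                writer.writerow([t.variable, lab, cnt, t.n, f"{pct:.1f}"])


def _association_row_dict(row: FactorAssociation) -> dict:
    d: dict = {"factor": row.factor, "computable": row.computable, "note": row.note}
    if row.result is not None:
        r = row.result
        d.update(
            statistic=r.statistic,
            df=r.df,
            p_asymptotic=r.p_asymptotic,
            p_monte_carlo=r.p_monte_carlo,
            mc_replicates=r.mc_replicates,
            p_value=r.p_value,
            mc_used=row.mc_used,
            cramers_v=r.cramers_v,
            v_ci_low=r.v_ci_low,
            v_ci_high=r.v_ci_high,
            effect_label=r.effect_label,
            significant=row.significant,
        )
    return d


def _write_association_csv(rows: Sequence[FactorAssociation], path: Path) -> None:
    cols = [
        "factor",
        "computable",
        "statistic",
        "df",
        "p_asymptotic",
        "p_monte_carlo",
        "p_value",
        "mc_used",
        "cramers_v",
        "v_ci_low",
        "v_ci_high",
        "effect_label",
        "significant",
        "note",
    ]
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols, extrasaction="ignore")
        writer.writeheader()
        for row in rows:
            writer.writerow(_association_row_dict(row))


@dataclass
class PipelineResult:
    out_dir: Path
    records: list[ArticleRecord]
    scorecards: list[ScoreCard]
    descriptives: list[FrequencyTable]
    decomposition: ErrorDecomposition
    associations: list[FactorAssociation]
    manifest: dict


def run_pipeline(
    out_dir: Union[str, Path],
    config: Optional[CorpusConfig] = None,
    corpus_path: Optional[Union[str, Path]] = None,
    seed: Optional[int] = None,
    weights: Weights = DEFAULT_WEIGHTS,
    factors: Sequence[str] = DEFAULT_FACTORS,
    mc_replicates: int = 10_000,
    bootstrap_replicates: int = 1000,
) -> PipelineResult:
    """Run simulate/load -> score -> summarize -> associate, writing a
    report bundle (CSV/JSON plus a manifest) under ``out_dir``.

    Exactly one corpus source is used: ``corpus_path`` if given, otherwise a
    synthetic corpus from ``config`` (default config when omitted).  ``seed``
    overrides the config seed and also seeds the resampling stages.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    simulated = corpus_path is None
    if simulated:
        cfg = config if config is not None else default_config()
        if seed is not None:
            cfg = cfg.model_copy(update={"seed": seed})
        logger.info("simulate: generating %d articles (seed %d)", cfg.n_articles, cfg.seed)
        records = generate_corpus(cfg)
        write_articles(records, out_dir / "corpus.csv")
        analysis_seed = cfg.seed
        config_dump = cfg.model_dump(mode="json")
    else:
        logger.info("load: reading corpus from %s", corpus_path)
        records = read_articles(corpus_path)
        analysis_seed = seed if seed is not None else 0
        config_dump = None
    if not records:
        raise ValueError("pipeline requires a nonempty corpus")

    logger.info("score: scoring %d articles", len(records))
    scorecards = score_corpus(records, weights)
    write_scorecards_csv(scorecards, out_dir / "scorecards.csv")
    write_scorecards_json(scorecards, out_dir / "scorecards.json")

    logger.info("summarize: descriptive tables and error decomposition")
    descriptives = summarize_descriptives(records, scorecards)
    _write_descriptives_csv(descriptives, out_dir / "descriptives.csv")
    decomposition = error_decomposition(scorecards)
    (out_dir / "error_decomposition.json").write_text(
        json.dumps(decomposition.__dict__, indent=2), encoding="utf-8"
    )

    logger.info("associate: %d factors vs outcome", len(factors))
    associations = association_table(
        records,
        scorecards,
        factors=factors,
        mc_replicates=mc_replicates,
        bootstrap_replicates=bootstrap_replicates,
        seed=analysis_seed,
    )
    _write_association_csv(associations, out_dir / "associations.csv")
    (out_dir / "associations.json").write_text(
        json.dumps([_association_row_dict(r) for r in associations], indent=2),
        encoding="utf-8",
    )

    from importlib.metadata import version, PackageNotFoundError

    try:
        pkg_version = version("statrigor")
    except PackageNotFoundError:
        pkg_version = "unknown"
    manifest = {
        "package": "statrigor",
        "version": pkg_version,
        "simulated": simulated,
        "corpus_path": str(corpus_path) if corpus_path else None,
        "config": config_dump,
        "n_articles": len(records),
        "analysis_seed": analysis_seed,
        "weights": weights.__dict__,
        "factors": list(factors),
        "mc_replicates": mc_replicates,
        "bootstrap_replicates": bootstrap_replicates,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return PipelineResult(
        out_dir=out_dir,
        records=list(records),
        scorecards=scorecards,
        descriptives=descriptives,
        decomposition=decomposition,
        associations=associations,
        manifest=manifest,
    )
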