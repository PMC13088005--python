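"""Article-level data model for the statistical-rigor audit.

Each appraised article is coded as a row of categorical responses: which
journal and year it comes from, whether a statistician was involved, and the
methodological characteristics that feed the five scoring domains (test
selection, sample-size justification, assumption testing, examiner
calibration, and interpretation of results).  The model enforces the
structural consistency rules of the coding scheme — e.g. a calibration
*quality* judgment exists only when calibration was mentioned at all — so
that downstream scoring never sees an incoherent record.
"""

from __future__ import annotations

import csv
import enum
import typing
from dataclasses import dataclass, fields as _dc_fields
from pathlib import Path
from typing import Iterable, Sequence, Union

__all__ = [
    "AuditError",
    "SchemaError",
    "RowError",
    "RecordValidationError",
    "Journal",
    "Continent",
    "VariableType",
    "GroupsClass",
    "TestPattern",
    "TestVariableMatch",
    "AssumptionsRequired",
    "IndependenceStatus",
    "ConditionalAssumptionStatus",
    "CalibrationQuality",
    "CIStatus",
    "NonsigDiscussion",
    "ArticleRecord",
    "COLUMNS",
    "validate_record",
    "validate_corpus",
    "read_articles",
    "write_articles",
]


class AuditError(ValueError):
    """Base class for audit data errors."""


class SchemaError(AuditError):
    """CSV header does not match the documented column set."""


class RowError(AuditError):
    """A row holds a token that does not parse into its column's type."""

    def __init__(self, row: int, column: str, token: str, message: str):
        self.row = row
        self.column = column
        self.token = token
        super().__init__(f"row {row}, column {column!r}: {message} (got {token!r})")


class RecordValidationError(AuditError):
    """One or more records violate structural invariants."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__(
            "invalid audit records:\n" + "\n".join(f"  - {v}" for v in violations)
        )


class Journal(str, enum.Enum):
    JOP = "jop"
    IJOP = "ijop"
    JPD = "jpd"


class Continent(str, enum.Enum):
    ASIA = "asia"
    EUROPE = "europe"
    NORTH_AMERICA = "north_america"
    SOUTH_AMERICA = "south_america"
    AFRICA = "africa"
    AUSTRALIA = "australia"


class VariableType(str, enum.Enum):
    CONTINUOUS = "continuous"
    CATEGORICAL = "categorical"
    ORDINAL = "ordinal"
    MIXED = "mixed"


class GroupsClass(str, enum.Enum):
    LT3 = "lt3"
    GE3 = "ge3"


class TestPattern(str, enum.Enum):
    SINGLE = "single"
    MULTIPLE = "multiple"


class TestVariableMatch(str, enum.Enum):
    __test__ = False  # keep pytest from collecting this domain enum

    APPROPRIATE = "appropriate"
    INAPPROPRIATE = "inappropriate"


class AssumptionsRequired(str, enum.Enum):
    """Assumptions the article's primary test carries.

    Non-parametric analyses require only independence of observations;
    parametric analyses additionally require normality and homogeneity of
    variance.
    """

    INDEPENDENCE_ONLY = "independence_only"
    INDEPENDENCE_NORMALITY_HOMOGENEITY = "independence_normality_homogeneity"


class IndependenceStatus(str, enum.Enum):
    VIOLATED = "violated"
    MAINTAINED = "maintained"
    UNCLEAR = "unclear"


class ConditionalAssumptionStatus(str, enum.Enum):
    """Status of normality / homogeneity testing, conditional on need."""

    NOT_REQUIRED_TESTED = "not_required_tested"
    NOT_REQUIRED_NOT_TESTED = "not_required_not_tested"
    REQUIRED_NOT_TESTED = "required_not_tested"
    REQUIRED_TESTED_SATISFIED = "required_tested_satisfied"


#: Statuses admissible when the primary test is non-parametric.
NOT_REQUIRED_STATUSES = frozenset(
    {
        ConditionalAssumptionStatus.NOT_REQUIRED_TESTED,
        ConditionalAssumptionStatus.NOT_REQUIRED_NOT_TESTED,
    }
)

#: Statuses admissible when the primary test is parametric.
REQUIRED_STATUSES = frozenset(
    {
        ConditionalAssumptionStatus.REQUIRED_NOT_TESTED,
        ConditionalAssumptionStatus.REQUIRED_TESTED_SATISFIED,
    }
)


class CalibrationQuality(str, enum.Enum):
    APPROPRIATE = "appropriate"
    INAPPROPRIATE = "inappropriate"
    NOT_APPLICABLE = "not_applicable"


class CIStatus(str, enum.Enum):
    NOT_REPORTED = "not_reported"
    REPORTED_NOT_INTERPRETED = "reported_not_interpreted"
    REPORTED_INTERPRETED = "reported_interpreted"


class NonsigDiscussion(str, enum.Enum):
    BRIEF = "brief"
    FULL = "full"


@dataclass(frozen=True)
class ArticleRecord:
    """One appraised article: bibliographic strata plus checklist responses."""

    article_id: str
    journal: Journal
    year: int
    statistician_involved: bool
    continent: Continent
    dependent_var_type: VariableType
    independent_var_type: VariableType
    n_groups_class: GroupsClass
    test_pattern: TestPattern
    test_variable_match: TestVariableMatch
    sample_size_reported: bool
    assumptions_required: AssumptionsRequired
    independence_status: IndependenceStatus
    normality_status: ConditionalAssumptionStatus
    homogeneity_status: ConditionalAssumptionStatus
    calibration_mentioned: bool
    calibration_quality: CalibrationQuality
    p_values_reported: bool
    ci_status: CIStatus
    nonsig_discussion: NonsigDiscussion
    limitations_discussed: bool
    assumption_violations_reported: bool


#: CSV column order; exactly the record fields, in declaration order.
COLUMNS: tuple[str, ...] = tuple(f.name for f in _dc_fields(ArticleRecord))

YEAR_MIN, YEAR_MAX = 2019, 2024

_FIELD_TYPES = typing.get_type_hints(ArticleRecord)
_ENUM_FIELDS = {
    name: tp
    for name, tp in _FIELD_TYPES.items()
    if isinstance(tp, type) and issubclass(tp, enum.Enum)
}
_BOOL_FIELDS = frozenset(name for name, tp in _FIELD_TYPES.items() if tp is bool)


def validate_record(record: ArticleRecord) -> list[str]:
    """Check structural invariants; return human-readable violations.

    Pure and total: any in-range combination of enum values yields a list
    (possibly empty) and never an exception.
    """
    v: list[str] = []
    rid = record.article_id
    if not (YEAR_MIN <= record.year <= YEAR_MAX):
        v.append(f"{rid}: year {record.year} outside [{YEAR_MIN}, {YEAR_MAX}]")
    # Calibration quality exists iff calibration was mentioned.
    if record.calibration_mentioned:
        if record.calibration_quality is CalibrationQuality.NOT_APPLICABLE:
            v.append(
                f"{rid}: calibration_mentioned=true but calibration_quality=not_applicable"
            )
    else:
        if record.calibration_quality is not CalibrationQuality.NOT_APPLICABLE:
            v.append(
                f"{rid}: calibration_mentioned=false requires "
                f"calibration_quality=not_applicable, got "
                f"{record.calibration_quality.value}"
            )
    # Normality / homogeneity statuses must match whether the test needs them.
    if record.assumptions_required is AssumptionsRequired.INDEPENDENCE_ONLY:
        allowed, tag = NOT_REQUIRED_STATUSES, "not_required_*"
    else:
        allowed, tag = REQUIRED_STATUSES, "required_*"
    for field in ("normality_status", "homogeneity_status"):
        status = getattr(record, field)
        if status not in allowed:
            v.append(
                f"{rid}: assumptions_required={record.assumptions_required.value} "
                f"requires {field} in {tag}, got {status.value}"
            )
    return v


def validate_corpus(records: Iterable[ArticleRecord]) -> list[str]:
    """Collect per-record violations plus duplicate-id violations."""
    violations: list[str] = []
    seen: set[str] = set()
    for rec in records:
        violations.extend(validate_record(rec))
        if rec.article_id in seen:
            violations.append(f"duplicate article_id {rec.article_id!r}")
        seen.add(rec.article_id)
    return violations


def _parse_bool(token: str) -> bool:
    if token == "true":
        return True
    if token == "false":
        return False
    raise ValueError("expected 'true' or 'false'")


def _parse_field(name: str, token: str, row: int):
    try:
        if name == "article_id":
            if not token:
                raise ValueError("empty article_id")
            return token
        if name == "year":
            return int(token)
        if name in _BOOL_FIELDS:
            return _parse_bool(token)
        enum_type = _ENUM_FIELDS[name]
        try:
            return enum_type(token)
        except ValueError:
            valid = ", ".join(m.value for m in enum_type)
            raise ValueError(f"not one of {{{valid}}}") from None
    except ValueError as exc:
        raise RowError(row, name, token, str(exc)) from None


def read_articles(
    path: Union[str, Path], *, strict: bool = True
) -> list[ArticleRecord]:
    """Read a validated audit corpus from CSV, preserving row order.

    With ``strict=True`` (the default) any structural-invariant violation or
    duplicate id raises :class:`RecordValidationError`.  With
    ``strict=False`` the parsed records are returned regardless and the
    caller may inspect them with :func:`validate_corpus`; tokens that do not
    parse at all still raise.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, expected header row") from None
        if tuple(header) != COLUMNS:
            missing = [c for c in COLUMNS if c not in header]
            extra = [c for c in header if c not in COLUMNS]
            raise SchemaError(
                f"{path}: header mismatch; missing columns {missing}, "
                f"unexpected columns {extra}"
            )
        records: list[ArticleRecord] = []
        for i, row in enumerate(reader, start=2):  # 1-based, after header
            if len(row) != len(COLUMNS):
                raise SchemaError(
                    f"{path}: row {i} has {len(row)} fields, expected {len(COLUMNS)}"
                )
            values = {
                name: _parse_field(name, token, i)
                for name, token in zip(COLUMNS, row)
            }
            records.append(ArticleRecord(**values))
    if strict:
        violations = validate_corpus(records)
        if violations:
            raise RecordValidationError(violations)
    return records


def _format_field(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, enum.Enum):
        return value.value
    return str(value)


def write_articles(records: Sequence[ArticleRecord], path: Union[str, Path]) -> Path:
    """Write records to CSV with the documented header and lowercase tokens."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for rec in records:
            writer.writerow([_format_field(getattr(rec, c)) for c in COLUMNS])
    return path
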