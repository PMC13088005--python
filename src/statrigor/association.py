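"""Categorical inference layer for the audit.

Covers the tests the audit reports: chi-square goodness of fit against
specified cell probabilities, Pearson's chi-square test of independence
(no continuity correction), Monte Carlo exact p-values for sparse tables
(triggered when more than 20% of expected cell counts fall below 5),
Cramér's V with nonparametric percentile-bootstrap confidence intervals,
Cohen's effect-size labels for V, and unweighted Cohen's kappa for
inter-rater agreement.

The Monte Carlo null holds row margins fixed and draws each row from a
multinomial over the pooled column proportions; the Pearson statistic is
then recomputed on every simulated table from that table's own margins
(exactly as for the observed table), so its null distribution carries the
usual (r-1)(c-1) degrees of freedom.  The p-value uses the add-one
estimator (1 + #{T_sim >= T_obs}) / (R + 1), which can never return zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "chisq_gof",
    "chisq_independence",
    "expected_counts",
    "needs_monte_carlo",
    "monte_carlo_pvalue",
    "cramers_v",
    "bootstrap_ci_cramers_v",
    "effect_size_label",
    "cohens_kappa",
]


@dataclass
class ContingencyTable:
    """Observed counts over one or two categorical factors.

    A one-row table encodes a goodness-of-fit observation vector.
    """

    counts: np.ndarray
    row_labels: Sequence[str] = ()
    col_labels: Sequence[str] = ()

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.number):
            raise ValueError("counts must be nonnegative numbers")
        if not np.any(self.counts):
            raise ValueError("table must have at least one nonzero cell")
        r, c = self.counts.shape
        self.row_labels = list(self.row_labels) or [str(i) for i in range(r)]
        self.col_labels = list(self.col_labels) or [str(j) for j in range(c)]
        if len(self.row_labels) != r or len(self.col_labels) != c:
            raise ValueError("label lists must match table dimensions")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_pairs(cls, xs: Sequence, ys: Sequence) -> "ContingencyTable":
        """Cross-tabulate paired categorical observations.

        Levels are the sorted distinct values observed on each axis, so all
        margins are positive by construction.
        """
        if len(xs) != len(ys):
            raise ValueError("paired observations must have equal length")
        if len(xs) == 0:
            raise ValueError("no observations")
        x = np.asarray([str(v) for v in xs])
        y = np.asarray([str(v) for v in ys])
        row_labels, xi = np.unique(x, return_inverse=True)
        col_labels, yi = np.unique(y, return_inverse=True)
        r, c = len(row_labels), len(col_labels)
        counts = np.bincount(xi * c + yi, minlength=r * c).reshape(r, c)
        return cls(counts, list(row_labels), list(col_labels))


@dataclass
class AssociationResult:
    """Outcome of a chi-square analysis, optionally with effect size."""

    statistic: float
    df: int
    p_asymptotic: float
    p_monte_carlo: Optional[float] = None
    mc_replicates: Optional[int] = None
    cramers_v: Optional[float] = None
    v_ci_low: Optional[float] = None
    v_ci_high: Optional[float] = None
    effect_label: Optional[str] = None

    @property
    def p_value(self) -> float:
        """Monte Carlo p when computed, otherwise the asymptotic p."""
        return self.p_monte_carlo if self.p_monte_carlo is not None else self.p_asymptotic


def chisq_gof(
    observed: Sequence[float], expected_probs: Optional[Sequence[float]] = None
) -> AssociationResult:
    """Chi-square goodness of fit of observed counts to cell probabilities.

    ``expected_probs`` defaults to uniform; it must sum to 1 and leave no
    expected cell at zero.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 1 or obs.size < 2:
        raise ValueError("observed must be a 1-D vector with >= 2 cells")
    k = obs.size
    if expected_probs is None:
        probs = np.full(k, 1.0 / k)
    else:
        probs = np.asarray(expected_probs, dtype=float)
        if probs.size != k:
            raise ValueError("expected_probs length must match observed")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("expected_probs must sum to 1")
    expected = obs.sum() * probs
    if np.any(expected <= 0):
        raise ValueError("every expected cell count must be positive")
    stat, p = stats.chisquare(obs, f_exp=expected)
    return AssociationResult(statistic=float(stat), df=k - 1, p_asymptotic=float(p))


def _check_margins(table: ContingencyTable) -> tuple[np.ndarray, np.ndarray]:
    counts = table.counts
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    for margin, labels, axis in ((rows, table.row_labels, "row"), (cols, table.col_labels, "column")):
        zero = np.flatnonzero(margin == 0)
        if zero.size:
            names = ", ".join(str(labels[i]) for i in zero)
            raise ValueError(f"empty {axis} level(s): {names}")
    return rows, cols


def expected_counts(table: ContingencyTable) -> np.ndarray:
    """Expected counts under independence: E_ij = r_i * c_j / n."""
    rows, cols = _check_margins(table)
    return np.outer(rows, cols) / table.n


def chisq_independence(table: ContingencyTable) -> AssociationResult:
    """Pearson's chi-square test of independence, no continuity correction."""
    counts = table.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("independence test requires at least a 2x2 table")
    _check_margins(table)
    res = stats.chi2_contingency(counts, correction=False)
    return AssociationResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_asymptotic=float(res.pvalue),
    )


def needs_monte_carlo(table: ContingencyTable) -> bool:
    """True iff strictly more than 20% of expected cell counts fall below 5."""
    expected = expected_counts(table)
    return float(np.mean(expected < 5.0)) > 0.20


def monte_carlo_pvalue(
    table: ContingencyTable, replicates: int = 100_000, seed: int = 0
) -> float:
    """Monte Carlo exact p-value for independence, fixed row margins.

    Each replicate redraws every row as a multinomial over the pooled column
    proportions, then the Pearson statistic is recomputed from the simulated
    table's own margins (cells whose expected count is zero — an empty
    simulated column — contribute zero, the degenerate-table convention).
    Returns the add-one estimate (1 + #{T >= T_obs}) / (replicates + 1).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    counts = table.counts.astype(float)
    rows, cols = _check_margins(table)
    n = table.n
    col_probs = cols / n
    expected = np.outer(rows, cols) / n
    obs_stat = float(((counts - expected) ** 2 / expected).sum())

    rng = np.random.default_rng(seed)
    r, c = counts.shape
    # draws[i]: (replicates, c) simulated counts for row i
    draws = np.stack(
        [rng.multinomial(int(rows[i]), col_probs, size=replicates) for i in range(r)],
        axis=1,
    ).astype(float)  # (replicates, r, c)
    sim_cols = draws.sum(axis=1)  # (replicates, c)
    sim_expected = rows[None, :, None] * sim_cols[:, None, :] / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (draws - sim_expected) ** 2 / sim_expected
    terms[sim_expected == 0] = 0.0
    sim_stat = terms.sum(axis=(1, 2))
    hits = int(np.count_nonzero(sim_stat >= obs_stat - 1e-12))
    return (1 + hits) / (replicates + 1)


def cramers_v(table: ContingencyTable) -> float:
    """Cramér's V = sqrt(chi2 / (n * (min(r, c) - 1)))."""
    r, c = table.counts.shape
    if r < 2 or c < 2:
        raise ValueError("Cramér's V requires at least a 2x2 table")
    chi2 = chisq_independence(table).statistic
    return float(math.sqrt(chi2 / (table.n * (min(r, c) - 1))))


def _v_from_codes(xi: np.ndarray, yi: np.ndarray, r: int, c: int) -> Optional[float]:
    """Cramér's V from integer-coded pairs; None if either axis collapses."""
    counts = np.bincount(xi * c + yi, minlength=r * c).reshape(r, c).astype(float)
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    rmask = rows > 0
    cmask = cols > 0
    if rmask.sum() < 2 or cmask.sum() < 2:
        return None
    sub = counts[np.ix_(rmask, cmask)]
    rs, cs = rows[rmask], cols[cmask]
    n = counts.sum()
    expected = np.outer(rs, cs) / n
    chi2 = ((sub - expected) ** 2 / expected).sum()
    return float(math.sqrt(chi2 / (n * (min(rmask.sum(), cmask.sum()) - 1))))


def bootstrap_ci_cramers_v(
    xs: Sequence,
    ys: Sequence,
    replicates: int = 1000,
    seed: int = 0,
    collapse: str = "redraw",
) -> tuple[float, float]:
    """Percentile-bootstrap 95% CI for Cramér's V on paired observations.

    Records are resampled with replacement n-from-n; V is recomputed per
    replicate and the 2.5th/97.5th percentiles returned.  A replicate whose
    resample collapses a level (leaving < 2 observed levels on an axis) is
    redrawn by default (``collapse='redraw'``) or scored as V = 0 with
    ``collapse='zero'``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if collapse not in ("redraw", "zero"):
        raise ValueError("collapse must be 'redraw' or 'zero'")
    x = np.asarray([str(v) for v in xs])
    y = np.asarray([str(v) for v in ys])
    if x.size != y.size:
        raise ValueError("paired observations must have equal length")
    xlab, xi = np.unique(x, return_inverse=True)
    ylab, yi = np.unique(y, return_inverse=True)
    r, c = len(xlab), len(ylab)
    if r < 2 or c < 2:
        raise ValueError("need >= 2 distinct levels observed on each axis")
    n = x.size

    rng = np.random.default_rng(seed)
    values = np.empty(replicates)
    filled = 0
    attempts = 0
    max_attempts = 1000 * replicates
    while filled < replicates:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "bootstrap could not draw enough non-degenerate resamples; "
                "too few records to preserve 2 levels per axis"
            )
        idx = rng.integers(0, n, size=n)
        v = _v_from_codes(xi[idx], yi[idx], r, c)
        if v is None:
            if collapse == "redraw":
                continue
            v = 0.0
        values[filled] = v
        filled += 1
    low, high = np.percentile(values, [2.5, 97.5])
    return float(low), float(high)


def effect_size_label(v: float) -> str:
    """Cohen's interpretation of Cramér's V (small 0.1, medium 0.3, large 0.5),
    with left-closed bins at the thresholds."""
    if not (0.0 <= v <= 1.0 + 1e-12):
        raise ValueError(f"v must lie in [0, 1], got {v!r}")
    if v < 0.1:
        return "negligible"
    if v < 0.3:
        return "small"
    if v < 0.5:
        return "medium"
    return "large"


def cohens_kappa(ratings_a: Sequence, ratings_b: Sequence) -> float:
    """Unweighted Cohen's kappa between two raters' categorical labels.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and p_e
    the chance agreement from the product of marginals.  When both raters
    are constant with identical marginals (p_e = 1) kappa is undefined and
    NaN is returned.
    """
    a = [str(v) for v in ratings_a]
    b = [str(v) for v in ratings_b]
    if len(a) != len(b):
        raise ValueError("rating sequences must have equal length")
    if not a:
        raise ValueError("rating sequences must be nonempty")
    labels = sorted(set(a) | set(b))
    index = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    counts = np.zeros((k, k))
    for va, vb in zip(a, b):
        counts[index[va], index[vb]] += 1
    n = counts.sum()
    p_o = np.trace(counts) / n
    p_e = float((counts.sum(axis=1) / n) @ (counts.sum(axis=0) / n))
    if abs(1.0 - p_e) < 1e-12:
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))
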