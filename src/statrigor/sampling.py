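"""Stratified sampling of an article frame and margin-of-error estimation.

The sampling design mirrors a feasibility-driven audit: within each
journal-by-year stratum, entries receive fresh uniform random keys, are
sorted by ascending key, and the top ``fraction`` (rounded half-up, never
fewer than one per nonempty stratum) are selected.  Per-stratum selection
counts therefore depend only on stratum sizes, never on the draw.

Precision of a proportion estimate is summarized by the standard
margin of error, MOE = z * sqrt(p * (1 - p) / n), with z = 1.96 for 95%
confidence and no finite-population correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .articles import ArticleRecord, Journal

__all__ = [
    "FrameEntry",
    "MOEResult",
    "frame_from_records",
    "stratified_sample",
    "margin_of_error",
]


@dataclass(frozen=True)
class FrameEntry:
    """One article in the eligible-article frame."""

    article_id: str
    journal: Journal
    year: int
    random_key: Optional[float] = None  # assigned during a sampling run


@dataclass(frozen=True)
class MOEResult:
    p: float
    n: int
    z: float
    moe: float


def frame_from_records(records: Iterable[ArticleRecord]) -> list[FrameEntry]:
    """Build a sampling frame (id, journal, year) from full audit records."""
    return [FrameEntry(r.article_id, r.journal, r.year) for r in records]


def _round_half_up(x: float) -> int:
    # small epsilon guards against float representation of fraction * n
    return int(math.floor(x + 0.5 + 1e-9))


def stratum_take(n_stratum: int, fraction: float) -> int:
    """Number selected from a stratum of size ``n_stratum``: round-half-up
    with a floor of one, so every journal-year remains represented."""
    return max(1, _round_half_up(fraction * n_stratum))


def stratified_sample(
    frame: Sequence[FrameEntry], fraction: float, seed: int
) -> list[FrameEntry]:
    """Select the top ``fraction`` of each (journal, year) stratum by
    ascending freshly drawn random key.

    Deterministic for a fixed seed; ties in the (continuous) keys break by
    article_id.  Returns the union over strata, ordered by stratum then key.
    """
    if not frame:
        raise ValueError("sampling frame is empty")
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction!r}")
    ids = [e.article_id for e in frame]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate article_id in frame")

    strata: dict[tuple[str, int], list[FrameEntry]] = {}
    for entry in frame:
        strata.setdefault((entry.journal.value, entry.year), []).append(entry)

    rng = np.random.default_rng(seed)
    selected: list[FrameEntry] = []
    for key in sorted(strata):
        members = strata[key]
        keys = rng.random(len(members))
        keyed = [
            FrameEntry(e.article_id, e.journal, e.year, float(k))
            for e, k in zip(members, keys)
        ]
        keyed.sort(key=lambda e: (e.random_key, e.article_id))
        selected.extend(keyed[: stratum_take(len(members), fraction)])
    return selected


def margin_of_error(p: float, n: int, z: float = 1.96) -> MOEResult:
    """Margin of error for a proportion: z * sqrt(p(1-p)/n)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p!r}")
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    if z <= 0:
        raise ValueError(f"z must be positive, got {z!r}")
    return MOEResult(p=p, n=n, z=z, moe=z * math.sqrt(p * (1.0 - p) / n))
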