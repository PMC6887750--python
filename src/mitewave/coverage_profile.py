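"""Per-position query coverage from hit records, and low-coverage drop windows.

Coverage counts alignment spans from hit coordinates (gaps inside a hit
count as covered, a stated dialect difference from per-column alignment
views). Drop windows — maximal runs whose coverage falls below a relative
threshold of the median non-zero coverage — are diagnostic of internal
deletion-derivative variants in a mixed family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import HitRecord

log = logging.getLogger(__name__)

__all__ = ["CoverageProfile", "Drop", "profile", "find_drops"]


@dataclass(frozen=True)
class Drop:
    """A maximal low-coverage window on the query element."""

    start: int
    end: int
    mean_fraction: float

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class CoverageProfile:
    query_id: str
    query_length: int
    counts: np.ndarray
    drops: list[Drop] = field(default_factory=list)


def profile(hits: Sequence[HitRecord], query_length: int) -> CoverageProfile:
    """Count, per query position, the number of hits whose query interval contains it.

    All hits must share one ``query_id`` and lie within ``[0, query_length)``.
    ``counts.sum()`` equals the summed query-span lengths of the hits.
    """
    ids = {h.query_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"hits span multiple query ids: {sorted(ids)}")
    query_id = next(iter(ids)) if ids else ""
    delta = np.zeros(query_length + 1, dtype=np.int64)
    for h in hits:
        if h.query_start < 0 or h.query_end > query_length:
            raise ValueError(
                f"hit {h.query_id}:{h.query_start}-{h.query_end} exceeds "
                f"query length {query_length}"
            )
        delta[h.query_start] += 1
        delta[h.query_end] -= 1
    counts = np.cumsum(delta[:-1])
    return CoverageProfile(query_id=query_id, query_length=query_length, counts=counts)


def find_drops(
    prof: CoverageProfile, rel_threshold: float = 0.1, min_width: int = 30
) -> list[Drop]:
    """Maximal runs where coverage falls below ``rel_threshold`` x median non-zero coverage.

    Runs shorter than ``min_width`` are ignored. ``mean_fraction`` is the
    run's mean coverage divided by the median non-zero coverage. With
    ``rel_threshold == 0`` only exact-zero runs are reported. An all-zero
    profile yields an empty result (logged), not an error.
    """
    if not 0.0 <= rel_threshold <= 1.0:
        raise ValueError("rel_threshold outside [0, 1]")
    if min_width < 1:
        raise ValueError("min_width must be >= 1")
    counts = prof.counts
    nonzero = counts[counts > 0]
    if nonzero.size == 0:
        log.warning("all-zero coverage profile for %r: no drops reported", prof.query_id)
        return []
    median = float(np.median(nonzero))
    if rel_threshold == 0.0:
        below = counts == 0
    else:
        below = counts < rel_threshold * median
    drops: list[Drop] = []
    i = 0
    n = counts.size
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if j - i >= min_width:
                drops.append(Drop(i, j, float(counts[i:j].mean()) / median))
            i = j
        else:
            i += 1
    return drops
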