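"""Defragment hit records into element copies; coverage filter; variant calls.

Annotation tools report one interrupted element insertion as several
collinear fragments. ``merge_fragments`` chains them back into copies with
an explicit greedy rule; ``filter_by_coverage`` applies the strict >50%
query-coverage filter; ``assign_variant`` classifies each copy as the full
element or its internal-deletion derivative from how much of the deletion
window its fragments cover.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .io_formats import HitRecord
from .synthetic_data import MasterElement

__all__ = [
    "ElementCopy",
    "merge_fragments",
    "filter_by_coverage",
    "assign_variant",
    "assign_variants",
]


@dataclass(frozen=True)
class ElementCopy:
    """A defragmented genomic insertion of one element family."""

    copy_id: str
    family: str
    contig: str
    start: int
    end: int
    strand: str
    fragments: tuple[HitRecord, ...]
    query_coverage: float
    variant: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError("copy without fragments")
        if not 0.0 < self.query_coverage <= 1.0:
            raise ValueError(f"query_coverage {self.query_coverage} outside (0, 1]")
        for f in self.fragments:
            if (f.query_id, f.target_id, f.strand) != (self.family, self.contig, self.strand):
                raise ValueError("fragment family/contig/strand mismatch")
        if self.start > min(f.target_start for f in self.fragments) or self.end < max(
            f.target_end for f in self.fragments
        ):
            raise ValueError("copy interval does not span its fragments")

    @property
    def span(self) -> int:
        return self.end - self.start


def _union_length(intervals: Sequence[tuple[int, int]]) -> int:
    total = 0
    last_end = None
    for s, e in sorted(intervals):
        if last_end is None or s >= last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


def _admissible(
    prev: HitRecord, nxt: HitRecord, max_gap_bp: int, max_query_overlap_bp: int
) -> bool:
    """Chaining rule between two target-sorted fragments of one family/contig/strand.

    Genomic gap must be <= ``max_gap_bp`` (small target overlaps up to the
    query-overlap allowance are tolerated), and query intervals must be
    collinear with the strand: query order follows genomic order on "+",
    reversed on "-", with query overlap <= ``max_query_overlap_bp``.
    """
    gap = nxt.target_start - prev.target_end
    if gap > max_gap_bp or gap < -max_query_overlap_bp:
        return False
    if prev.strand == "+":
        return (
            nxt.query_start >= prev.query_end - max_query_overlap_bp
            and nxt.query_start > prev.query_start
        )
    return (
        nxt.query_end <= prev.query_start + max_query_overlap_bp
        and nxt.query_end < prev.query_end
    )


def merge_fragments(
    hits: Sequence[HitRecord],
    query_length: int,
    max_gap_bp: int = 500,
    max_query_overlap_bp: int = 20,
) -> list[ElementCopy]:
    """Chain collinear fragments into copies, greedily left-to-right.

    Fragments are grouped by (family, contig, strand) and sorted by target
    start; each chain repeatedly absorbs the nearest admissible next
    fragment. Every hit ends up in exactly one copy; unchainable hits
    become single-fragment copies.
    """
    if query_length <= 0:
        raise ValueError("query_length must be > 0")
    groups: dict[tuple[str, str, str], list[HitRecord]] = {}
    for h in hits:
        groups.setdefault((h.query_id, h.target_id, h.strand), []).append(h)

    copies: list[ElementCopy] = []
    for (family, contig, strand), group in sorted(groups.items()):
        group.sort(key=lambda h: (h.target_start, h.target_end, h.query_start))
        used = [False] * len(group)
        for i in range(len(group)):
            if used[i]:
                continue
            chain = [group[i]]
            used[i] = True
            last = i
            while True:
                nxt = None
                for j in range(last + 1, len(group)):
                    if used[j]:
                        continue
                    if group[j].target_start - group[last].target_end > max_gap_bp:
                        break  # sorted by target_start: no nearer candidate follows
                    if _admissible(group[last], group[j], max_gap_bp, max_query_overlap_bp):
                        nxt = j
                        break
                if nxt is None:
                    break
                chain.append(group[nxt])
                used[nxt] = True
                last = nxt
            start = min(h.target_start for h in chain)
            end = max(h.target_end for h in chain)
            coverage = _union_length([(h.query_start, h.query_end) for h in chain])
            copies.append(
                ElementCopy(
                    copy_id=f"{family}|{contig}|{start}",
                    family=family,
                    contig=contig,
                    start=start,
                    end=end,
                    strand=strand,
                    fragments=tuple(chain),
                    query_coverage=coverage / query_length,
                )
            )
    copies.sort(key=lambda c: (c.contig, c.start, c.end))
    return copies


def filter_by_coverage(
    copies: Sequence[ElementCopy], min_fraction: float = 0.5
) -> list[ElementCopy]:
    """Keep copies whose query coverage is strictly greater than ``min_fraction``."""
    return [c for c in copies if c.query_coverage > min_fraction]


def assign_variant(
    copy: ElementCopy,
    master: MasterElement,
    derivative_max_fraction: float = 0.1,
    full_min_fraction: float = 0.5,
) -> str:
    """Classify a copy by how much of the master's deletion window it covers.

    ``deletion_derivative`` if less than 10% of the window is covered by
    the copy's query intervals, ``full`` if more than 50%, ``ambiguous``
    otherwise.
    """
    if master.deletion_window is None:
        raise ValueError("master has no deletion window")
    ds, de = master.deletion_window
    covered = _union_length(
        [
            (max(h.query_start, ds), min(h.query_end, de))
            for h in copy.fragments
            if h.query_start < de and h.query_end > ds
        ]
    )
    fraction = covered / (de - ds)
    if fraction < derivative_max_fraction:
        return "deletion_derivative"
    if fraction > full_min_fraction:
        return "full"
    return "ambiguous"


def assign_variants(
    copies: Sequence[ElementCopy],
    master: MasterElement,
    derivative_max_fraction: float = 0.1,
    full_min_fraction: float = 0.5,
) -> list[ElementCopy]:
    return [
        replace(
            c,
            variant=assign_variant(c, master, derivative_max_fraction, full_min_fraction),
        )
        for c in copies
    ]
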