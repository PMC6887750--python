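"""Genomic-context classification of element copies and independence tests.

A copy is "genic" when its interval shares at least one base with a gene
interval extended by a flank on both sides (half-open arithmetic, strand
ignored); "flank-only" when genic but missing the unextended gene. Species
-by-context independence uses Pearson's chi-square without continuity
correction; post-hoc pairwise 2x2 chi-square tests are Bonferroni
corrected over all pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import GeneFeature

log = logging.getLogger(__name__)

__all__ = [
    "ContextRow",
    "PairwiseResult",
    "genic_overlap",
    "independence_test",
    "posthoc_pairwise",
    "transcript_context",
]

_GENE_LEVEL_KINDS = ("gene", "lncRNA")


@dataclass(frozen=True)
class ContextRow:
    """Genic-context counts for one species."""

    species: str
    n_total: int
    n_genic: int
    n_gene_body: int
    n_flank_only: int

    def __post_init__(self) -> None:
        if self.n_genic > self.n_total:
            raise ValueError("n_genic exceeds n_total")
        if self.n_gene_body + self.n_flank_only != self.n_genic:
            raise ValueError("gene_body + flank_only must equal n_genic")

    @property
    def percent_genic(self) -> float:
        return 100.0 * self.n_genic / self.n_total if self.n_total else 0.0

    @property
    def n_non_genic(self) -> int:
        return self.n_total - self.n_genic


def _copy_interval(copy) -> tuple[str, int, int]:
    if isinstance(copy, tuple):
        return copy
    return (copy.contig, copy.start, copy.end)


def genic_overlap(
    copies: Sequence,
    genes: Sequence[GeneFeature],
    flank_bp: int = 5000,
    species: str = "sample",
    contig_lengths: Mapping[str, int] | None = None,
) -> ContextRow:
    """Classify copies as genic / flank-only / non-genic against gene intervals.

    ``copies`` may be ``(contig, start, end)`` tuples or objects with
    those attributes. Gene-level intervals are features of kind ``gene``
    or ``lncRNA``. Copies on contigs absent from the annotation count as
    non-genic with a logged warning.
    """
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        if g.feature_kind in _GENE_LEVEL_KINDS:
            by_contig.setdefault(g.contig, []).append((g.start, g.end))

    n_total = n_genic = n_body = 0
    unknown_contigs: set[str] = set()
    for copy in copies:
        contig, cs, ce = _copy_interval(copy)
        n_total += 1
        intervals = by_contig.get(contig)
        if intervals is None:
            unknown_contigs.add(contig)
            continue
        clip = contig_lengths.get(contig) if contig_lengths else None
        genic = body = False
        for gs, ge in intervals:
            fs = max(0, gs - flank_bp)
            fe = ge + flank_bp if clip is None else min(clip, ge + flank_bp)
            if fs < ce and cs < fe:
                genic = True
                if gs < ce and cs < ge:
                    body = True
                    break
        n_genic += genic
        n_body += body
    if unknown_contigs:
        log.warning(
            "%s: %d copy contigs absent from the gene annotation (counted non-genic): %s",
            species,
            len(unknown_contigs),
            sorted(unknown_contigs),
        )
    return ContextRow(
        species=species,
        n_total=n_total,
        n_genic=n_genic,
        n_gene_body=n_body,
        n_flank_only=n_genic - n_body,
    )


def independence_test(table: np.ndarray | Sequence[Sequence[int]]) -> tuple[float, int, float]:
    """Pearson chi-square test of species x {genic, non-genic} independence.

    No continuity correction. Returns ``(chi2, df, p)`` with
    ``df = (k - 1)`` for ``k`` species rows.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] != 2:
        raise ValueError(f"need a k x 2 table with k >= 2, got shape {t.shape}")
    if (t.sum(axis=1) == 0).any():
        raise ValueError("table has a zero row sum")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


@dataclass(frozen=True)
class PairwiseResult:
    species_i: str
    species_j: str
    chi2: float
    p_raw: float
    p_bonferroni: float
    significant: bool


def posthoc_pairwise(
    table: np.ndarray | Sequence[Sequence[int]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.01,
) -> list[PairwiseResult]:
    """All pairwise 2x2 chi-square tests with Bonferroni correction.

    ``p_bonferroni = min(1, p_raw * m)`` with ``m = k(k-1)/2`` comparisons.
    """
    t = np.asarray(table, dtype=float)
    k = t.shape[0]
    if k < 3:
        raise ValueError("post-hoc correction needs k >= 3 groups")
    if labels is None:
        labels = [f"group_{i}" for i in range(k)]
    m = k * (k - 1) // 2
    results: list[PairwiseResult] = []
    for i, j in combinations(range(k), 2):
        sub = t[[i, j], :]
        if (sub.sum(axis=0) == 0).any() or (sub.sum(axis=1) == 0).any():
            chi2, p = 0.0, 1.0
        else:
            res = stats.chi2_contingency(sub, correction=False)
            chi2, p = float(res.statistic), float(res.pvalue)
        p_bonf = min(1.0, p * m)
        results.append(
            PairwiseResult(labels[i], labels[j], chi2, p, p_bonf, p_bonf < alpha)
        )
    return results


_PRIORITY = ("CDS", "five_prime_UTR", "three_prime_UTR")


def transcript_context(
    copies: Sequence, features: Sequence[GeneFeature]
) -> dict[str, int]:
    """Classify copies overlapping transcripts by sub-feature.

    Each copy intersecting an mRNA is counted once, by the overlapped
    sub-feature with priority CDS > 5'UTR > 3'UTR ("other" when it hits an
    mRNA but none of its sub-features). lncRNA overlaps are counted
    separately; a copy can contribute to both tallies.
    """
    mrnas = [f for f in features if f.feature_kind == "mRNA"]
    lncs = [f for f in features if f.feature_kind == "lncRNA"]
    children: dict[str, list[GeneFeature]] = {}
    for f in features:
        if f.parent_id is not None and f.feature_kind in _PRIORITY:
            children.setdefault(f.parent_id, []).append(f)

    counts = {
        "mRNA_total": 0,
        "CDS": 0,
        "five_prime_UTR": 0,
        "three_prime_UTR": 0,
        "other": 0,
        "lncRNA": 0,
    }
    for copy in copies:
        contig, cs, ce = _copy_interval(copy)
        hit_kinds: set[str] = set()
        hit_mrna = False
        for m in mrnas:
            if m.contig == contig and m.start < ce and cs < m.end:
                hit_mrna = True
                for sub in children.get(m.id, []):
                    if sub.start < ce and cs < sub.end:
                        hit_kinds.add(sub.feature_kind)
        if hit_mrna:
            counts["mRNA_total"] += 1
            for kind in _PRIORITY:
                if kind in hit_kinds:
                    counts[kind] += 1
                    break
            else:
                counts["other"] += 1
        if any(l.contig == contig and l.start < ce and cs < l.end for l in lncs):
            counts["lncRNA"] += 1
    return counts
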