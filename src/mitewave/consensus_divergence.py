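"""Majority-rule consensus from an MSA and Jukes-Cantor divergence of copies.

The consensus caller is strict majority over {A, C, G, T, gap} per column
(N excluded from voting), ties broken A < C < G < T with gap losing ties;
gap-majority columns are dropped from the consensus string. Distances use
pairwise deletion: columns where either symbol is a gap or N are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConsensusProfile",
    "DivergenceSummary",
    "build_consensus",
    "p_distance",
    "jc_distance",
    "divergence_landscape",
    "pairwise_jc_matrix",
]

_VOTE_SYMBOLS = b"ACGT-"
_VOTE_ARR = np.frombuffer(_VOTE_SYMBOLS, dtype=np.uint8)

# bases that count as comparable sites in distance computations
_COMPARABLE = np.zeros(256, dtype=bool)
for _b in b"ACGT":
    _COMPARABLE[_b] = True


def _msa_to_array(msa: Sequence[tuple[str, str]]) -> np.ndarray:
    if not msa:
        raise ValueError("empty MSA")
    width = len(msa[0][1])
    for name, row in msa:
        if len(row) != width:
            raise ValueError(f"row {name!r} has width {len(row)}, expected {width}")
    data = "".join(row.upper() for _, row in msa).encode("ascii")
    return np.frombuffer(data, dtype=np.uint8).reshape(len(msa), width)


@dataclass
class ConsensusProfile:
    """Per-column symbol counts plus the derived majority-rule consensus."""

    counts: np.ndarray  # (width, 5) counts over A, C, G, T, gap
    column_kept: np.ndarray  # bool per column; False where gap wins the vote
    column_symbols: str  # per-column winner, '-' on dropped columns
    consensus: str  # gap-free consensus (kept columns only)


def build_consensus(msa: Sequence[tuple[str, str]]) -> ConsensusProfile:
    """Majority-rule consensus; see module docstring for the tie rules."""
    arr = _msa_to_array(msa)
    width = arr.shape[1]
    counts = np.zeros((width, 5), dtype=np.int64)
    for k, sym in enumerate(_VOTE_ARR):
        counts[:, k] = (arr == sym).sum(axis=0)
    base_counts = counts[:, :4]
    best_base = base_counts.argmax(axis=1)  # argmax returns first max: A < C < G < T
    best_base_count = base_counts.max(axis=1)
    kept = best_base_count >= counts[:, 4]  # gap loses ties
    winners = np.where(kept, _VOTE_ARR[best_base], ord("-")).astype(np.uint8)
    column_symbols = winners.tobytes().decode("ascii")
    consensus = winners[kept].tobytes().decode("ascii")
    return ConsensusProfile(
        counts=counts,
        column_kept=kept,
        column_symbols=column_symbols,
        consensus=consensus,
    )


def p_distance(row: str, other: str) -> float:
    """Observed proportion of differing sites, with pairwise deletion.

    Columns where either symbol is a gap, N or any non-ACGT character are
    excluded from numerator and denominator. Returns NaN when no columns
    are comparable (undefined, deliberately not 0).
    """
    if len(row) != len(other):
        raise ValueError(f"length mismatch: {len(row)} vs {len(other)}")
    a = np.frombuffer(row.upper().encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(other.upper().encode("ascii"), dtype=np.uint8)
    valid = _COMPARABLE[a] & _COMPARABLE[b]
    n = int(valid.sum())
    if n == 0:
        return math.nan
    mismatches = int((a[valid] != b[valid]).sum())
    return mismatches / n


def jc_distance(p: float) -> float:
    """Jukes-Cantor distance ``d = -(3/4) ln(1 - (4/3) p)``.

    Saturated inputs (``p >= 0.75``) return ``inf`` as a saturation marker
    and are excluded from aggregates; NaN propagates.
    """
    if math.isnan(p):
        return math.nan
    if p < 0:
        raise ValueError(f"p-distance {p} is negative")
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


@dataclass
class DivergenceSummary:
    """Per-copy divergences from the consensus plus aggregates.

    ``min`` is the youngest-copy statistic consumed by activity dating;
    the histogram uses 1% (0.01 substitutions/site) bins.
    """

    ids: list[str]
    p: np.ndarray
    jc: np.ndarray
    mean: float
    min: float
    max: float
    n_saturated: int
    hist_edges: np.ndarray
    hist_counts: np.ndarray


def divergence_landscape(
    msa: Sequence[tuple[str, str]], consensus: ConsensusProfile | None = None
) -> DivergenceSummary:
    """Jukes-Cantor divergence of every MSA row from the (given or built) consensus."""
    if consensus is None:
        consensus = build_consensus(msa)
    cons_cols = consensus.column_symbols
    ids = [name for name, _ in msa]
    p = np.array([p_distance(row, cons_cols) for _, row in msa])
    jc = np.array([jc_distance(v) for v in p])
    finite = np.isfinite(jc)
    n_saturated = int(np.sum(np.isinf(jc)))
    if finite.any():
        mean = float(jc[finite].mean())
        dmin = float(jc[finite].min())
        dmax = float(jc[finite].max())
        top = max(1.0, math.ceil(dmax * 100) / 100)
    else:
        mean = dmin = dmax = math.nan
        top = 1.0
    edges = np.arange(0.0, top + 0.01, 0.01)
    hist, _ = np.histogram(jc[finite], bins=edges)
    return DivergenceSummary(
        ids=ids,
        p=p,
        jc=jc,
        mean=mean,
        min=dmin,
        max=dmax,
        n_saturated=n_saturated,
        hist_edges=edges,
        hist_counts=hist,
    )


def pairwise_jc_matrix(
    msa: Sequence[tuple[str, str]]
) -> tuple[list[str], np.ndarray]:
    """All-against-all Jukes-Cantor distances between MSA rows.

    A distance-matrix export standing in for tree building; saturated
    pairs are reported as ``inf``.
    """
    names = [name for name, _ in msa]
    rows = [row for _, row in msa]
    n = len(rows)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = jc_distance(p_distance(rows[i], rows[j]))
            m[i, j] = m[j, i] = d
    return names, m
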