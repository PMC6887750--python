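"""Independent oracles used by the test suite.

Each oracle re-derives an expected value by a different route than the
implementation it checks: top-down memoized recursion for local alignment,
the hand Sum((O-E)^2/E) formula for chi-square, and exhaustive partition
search for fragment chaining.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

from scipy import stats

NEG = float("-inf")


def sw_best_score(
    q: str,
    s: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> float:
    """Best local-alignment score by top-down affine-state recursion."""
    n, m = len(q), len(s)

    @lru_cache(maxsize=None)
    def end_at(i: int, j: int, state: str) -> float:
        # best score of any local alignment ending exactly at (i, j) in `state`
        if state == "M":
            sub = match if q[i - 1] == s[j - 1] else mismatch
            prev = 0.0
            if i > 1 and j > 1:
                prev = max(
                    0.0,
                    end_at(i - 1, j - 1, "M"),
                    end_at(i - 1, j - 1, "X"),
                    end_at(i - 1, j - 1, "Y"),
                )
            return prev + sub
        if state == "X":  # gap in subject, consumes q[i-1]
            if i < 2:
                return NEG
            return max(end_at(i - 1, j, "M") + gap_open, end_at(i - 1, j, "X") + gap_extend)
        # state == "Y": gap in query, consumes s[j-1]
        if j < 2:
            return NEG
        return max(end_at(i, j - 1, "M") + gap_open, end_at(i, j - 1, "Y") + gap_extend)

    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = max(best, end_at(i, j, "M"))
    return best


def chi2_hand(table) -> tuple[float, int, float]:
    """Pearson chi-square by the literal Sum((O-E)^2/E) formula."""
    rows = [list(map(float, r)) for r in table]
    k, c = len(rows), len(rows[0])
    row_sums = [sum(r) for r in rows]
    col_sums = [sum(rows[i][j] for i in range(k)) for j in range(c)]
    total = sum(row_sums)
    chi2 = 0.0
    for i in range(k):
        for j in range(c):
            e = row_sums[i] * col_sums[j] / total
            if e > 0:
                chi2 += (rows[i][j] - e) ** 2 / e
    df = (k - 1) * (c - 1)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def _oracle_admissible(prev, nxt, max_gap_bp: int, max_query_overlap_bp: int) -> bool:
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


def min_chain_partition(hits, max_gap_bp: int = 500, max_query_overlap_bp: int = 20) -> int:
    """Minimum number of admissible chains covering all hits (exhaustive).

    Hits must share one (family, contig, strand) group. Processes hits in
    target order; each hit either extends an existing chain (any whose tail
    admits it) or opens a new one.
    """
    order = sorted(hits, key=lambda h: (h.target_start, h.target_end, h.query_start))
    best = [len(order)]

    def recurse(idx: int, tails: list) -> None:
        if len(tails) >= best[0]:
            return
        if idx == len(order):
            best[0] = min(best[0], len(tails))
            return
        h = order[idx]
        for t in range(len(tails)):
            if _oracle_admissible(tails[t], h, max_gap_bp, max_query_overlap_bp):
                saved = tails[t]
                tails[t] = h
                recurse(idx + 1, tails)
                tails[t] = saved
        tails.append(h)
        recurse(idx + 1, tails)
        tails.pop()

    recurse(0, [])
    return best[0]
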