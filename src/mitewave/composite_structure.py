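"""Dissect a MITE consensus into homologous segments and detect terminal inverted repeats.

Local alignment is Smith-Waterman with affine gaps and a deterministic
traceback (diagonal > up > left on ties). ``segment_map`` tiles the query
with discrete homology blocks by iterative best-hit extraction and query
masking, splitting alignments at long internal gaps so a bridged deletion
shows up as two flanking blocks. ``detect_tir`` aligns the 5' terminus
against the reverse complement of the 3' terminus under a cumulative
mismatch budget.
"""

from __future__ import annotations

from dataclasses import dataclass

from .consensus_divergence import jc_distance
from .synthetic_data import reverse_complement

__all__ = [
    "LocalAlignment",
    "HomologySegment",
    "TirCall",
    "local_align",
    "segment_map",
    "detect_tir",
    "structure_string",
]

_NEG = float("-inf")
_BLOCKED = -1e9  # masked query rows may never be part of an alignment
_DNA = set("ACGT")


@dataclass(frozen=True)
class LocalAlignment:
    """Best-scoring local alignment; intervals are 0-based half-open."""

    score: float
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    query_aln: str
    subject_aln: str

    @property
    def n_columns(self) -> int:
        return len(self.query_aln)


def local_align(
    query: str,
    subject: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> LocalAlignment | None:
    """Smith-Waterman with affine gaps; returns the single best local alignment.

    ``gap_open`` is charged for the first gapped position of a run and
    ``gap_extend`` for each further position. Characters outside ACGT on
    either sequence (e.g. the ``#`` mask) can never be aligned. Returns
    ``None`` when no alignment scores above zero.
    """
    q, s = query.upper(), subject.upper()
    n, m = len(q), len(s)
    if n == 0 or m == 0:
        return None

    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject (up)
    Iy = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (left)
    ptr_m = [[0] * (m + 1) for _ in range(n + 1)]  # 0 stop, 1 M, 2 Ix, 3 Iy
    ptr_x = [[0] * (m + 1) for _ in range(n + 1)]  # 1 open from M, 2 extend
    ptr_y = [[0] * (m + 1) for _ in range(n + 1)]  # 1 open from M, 3 extend

    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        qc = q[i - 1]
        q_ok = qc in _DNA
        Mi, Mp = M[i], M[i - 1]
        Xi, Xp = Ix[i], Ix[i - 1]
        Yi = Iy[i]
        pm, px, py = ptr_m[i], ptr_x[i], ptr_y[i]
        for j in range(1, m + 1):
            sc = s[j - 1]
            if q_ok and sc in _DNA:
                sub = match if qc == sc else mismatch
            else:
                sub = _BLOCKED
            # M: align q[i-1] with s[j-1]
            pm_val, px_val, py_val = Mp[j - 1], Xp[j - 1], Iy[i - 1][j - 1]
            prev, state = pm_val, 1
            if px_val > prev:
                prev, state = px_val, 2
            if py_val > prev:
                prev, state = py_val, 3
            if prev <= 0.0:
                prev, state = 0.0, 0
            val = prev + sub
            Mi[j] = val
            pm[j] = state
            if val > best:
                best, bi, bj = val, i, j
            # Ix: gap in subject, consume query char
            if q_ok:
                open_x = Mp[j] + gap_open
                ext_x = Xp[j] + gap_extend
                if open_x >= ext_x:
                    Xi[j], px[j] = open_x, 1
                else:
                    Xi[j], px[j] = ext_x, 2
            else:
                Xi[j] = _BLOCKED
                px[j] = 1
            # Iy: gap in query, consume subject char
            open_y = Mi[j - 1] + gap_open
            ext_y = Yi[j - 1] + gap_extend
            if open_y >= ext_y:
                Yi[j], py[j] = open_y, 1
            else:
                Yi[j], py[j] = ext_y, 3

    if best <= 0.0:
        return None

    # traceback from the best M cell
    i, j, state = bi, bj, 1
    qa: list[str] = []
    sa: list[str] = []
    while True:
        if state == 1:
            qa.append(q[i - 1])
            sa.append(s[j - 1])
            nxt = ptr_m[i][j]
            i -= 1
            j -= 1
            if nxt == 0:
                break
            state = nxt
        elif state == 2:
            qa.append(q[i - 1])
            sa.append("-")
            nxt = ptr_x[i][j]
            i -= 1
            state = 1 if nxt == 1 else 2
        else:
            qa.append("-")
            sa.append(s[j - 1])
            nxt = ptr_y[i][j]
            j -= 1
            state = 1 if nxt == 1 else 3

    return LocalAlignment(
        score=best,
        query_start=i,
        query_end=bi,
        subject_start=j,
        subject_end=bj,
        query_aln="".join(reversed(qa)),
        subject_aln="".join(reversed(sa)),
    )


@dataclass(frozen=True)
class HomologySegment:
    """A homology block between the dissected element and one subject sequence."""

    query_start: int
    query_end: int
    subject_id: str
    subject_start: int
    subject_end: int
    strand: str
    p_distance: float
    jc_distance: float
    score: float


def _alignment_pieces(
    aln: LocalAlignment,
    max_internal_gap: int,
    match: float,
    mismatch: float,
    gap_open: float,
    gap_extend: float,
) -> list[dict]:
    """Split an alignment at gap runs longer than ``max_internal_gap`` columns.

    Each piece is rescored with the affine scheme and trimmed of terminal
    gap columns; offsets locate it on both sequences.
    """
    cols = list(zip(aln.query_aln, aln.subject_aln))
    # indices of column ranges between over-long gap runs
    ranges: list[tuple[int, int]] = []
    start = 0
    run_char = None
    run_len = 0
    for idx, (qc, sc) in enumerate(cols):
        gap = "q" if qc == "-" else ("s" if sc == "-" else None)
        if gap is not None and gap == run_char:
            run_len += 1
        elif gap is not None:
            run_char, run_len = gap, 1
        else:
            if run_char is not None and run_len > max_internal_gap:
                ranges.append((start, idx - run_len))
                start = idx
            run_char, run_len = None, 0
    ranges.append((start, len(cols)))

    pieces = []
    for lo, hi in ranges:
        # trim terminal gap columns
        while lo < hi and ("-" in cols[lo]):
            lo += 1
        while hi > lo and ("-" in cols[hi - 1]):
            hi -= 1
        if lo >= hi:
            continue
        qpos = aln.query_start + sum(1 for qc, _ in cols[:lo] if qc != "-")
        spos = aln.subject_start + sum(1 for _, sc in cols[:lo] if sc != "-")
        score = 0.0
        q_len = s_len = matches = mismatches = 0
        in_gap = False
        for qc, sc in cols[lo:hi]:
            if qc == "-" or sc == "-":
                score += gap_extend if in_gap else gap_open
                in_gap = True
            else:
                score += match if qc == sc else mismatch
                matches += qc == sc
                mismatches += qc != sc
                in_gap = False
            q_len += qc != "-"
            s_len += sc != "-"
        compared = matches + mismatches
        p = mismatches / compared if compared else float("nan")
        pieces.append(
            {
                "score": score,
                "q0": qpos,
                "q1": qpos + q_len,
                "s0": spos,
                "s1": spos + s_len,
                "p": p,
            }
        )
    return pieces


def segment_map(
    mite: str,
    subjects: list[tuple[str, str]],
    min_score: float = 40.0,
    min_length: int = 30,
    max_internal_gap: int = 30,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> list[HomologySegment]:
    """Tile the element with homology blocks of the candidate parental sequences.

    Iteratively: align every subject (both strands) to the currently
    unmasked query, split the alignments at long internal gaps, take the
    best-scoring block passing the score/length thresholds, mask its query
    interval, repeat. Blocks therefore never overlap on the query.
    """
    if not subjects:
        raise ValueError("no subject sequences supplied")
    masked = list(mite.upper())
    segments: list[HomologySegment] = []
    while True:
        qstr = "".join(masked)
        best_piece = None
        best_meta = None
        for sid, sseq in subjects:
            fwd = sseq.upper()
            for strand, subj in (("+", fwd), ("-", reverse_complement(fwd))):
                aln = local_align(qstr, subj, match, mismatch, gap_open, gap_extend)
                if aln is None:
                    continue
                for piece in _alignment_pieces(
                    aln, max_internal_gap, match, mismatch, gap_open, gap_extend
                ):
                    if piece["score"] < min_score:
                        continue
                    if piece["q1"] - piece["q0"] < min_length:
                        continue
                    if best_piece is None or piece["score"] > best_piece["score"]:
                        best_piece = piece
                        best_meta = (sid, strand, len(fwd))
        if best_piece is None:
            break
        sid, strand, slen = best_meta
        s0, s1 = best_piece["s0"], best_piece["s1"]
        if strand == "-":
            s0, s1 = slen - best_piece["s1"], slen - best_piece["s0"]
        p = best_piece["p"]
        segments.append(
            HomologySegment(
                query_start=best_piece["q0"],
                query_end=best_piece["q1"],
                subject_id=sid,
                subject_start=s0,
                subject_end=s1,
                strand=strand,
                p_distance=p,
                jc_distance=jc_distance(p),
                score=best_piece["score"],
            )
        )
        for k in range(best_piece["q0"], best_piece["q1"]):
            masked[k] = "#"
    segments.sort(key=lambda seg: seg.query_start)
    return segments


@dataclass(frozen=True)
class TirCall:
    """A terminal-inverted-repeat call at the sequence termini."""

    length: int
    mismatches: int
    arm5_interval: tuple[int, int]
    arm3_interval: tuple[int, int]


def detect_tir(
    sequence: str,
    min_tir_length: int = 10,
    max_mismatch_fraction: float = 0.2,
) -> TirCall | None:
    """Detect terminal inverted repeats.

    The 5' terminus is compared base-by-base against the reverse
    complement of the 3' terminus, extending while the cumulative mismatch
    fraction stays within ``max_mismatch_fraction``. Among qualifying arm
    lengths >= ``min_tir_length`` the one maximizing matches - mismatches
    is reported (shortest on ties), so a clean TIR is not diluted by a
    noisy chance extension.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < 2 * min_tir_length:
        raise ValueError(
            f"sequence length {n} below 2 x min_tir_length ({2 * min_tir_length})"
        )
    rc3 = reverse_complement(seq)  # rc3[:k] is the reverse complement of the last k bases
    arm_max = n // 2
    mism = 0
    best: tuple[int, int] | None = None
    best_score = float("-inf")
    for k in range(1, arm_max + 1):
        if seq[k - 1] != rc3[k - 1]:
            mism += 1
        if mism > max_mismatch_fraction * k + 1e-12:
            break
        if k >= min_tir_length:
            score = (k - mism) - mism
            if score > best_score:
                best_score = score
                best = (k, mism)
    if best is None:
        return None
    length, mismatches = best
    return TirCall(
        length=length,
        mismatches=mismatches,
        arm5_interval=(0, length),
        arm3_interval=(n - length, n),
    )


def structure_string(
    element_length: int,
    tir: TirCall | None,
    segments: list[HomologySegment],
) -> str:
    """Render the element anatomy as a compact block string.

    Example: ``TIR5|marinerA[24-80]|sineB[300-540]|TIR3``.
    """
    parts: list[str] = []
    if tir is not None:
        parts.append("TIR5")
    for seg in segments:
        parts.append(f"{seg.subject_id}[{seg.query_start}-{seg.query_end}]")
    if tir is not None:
        parts.append("TIR3")
    return "|".join(parts) if parts else "(unresolved)"
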