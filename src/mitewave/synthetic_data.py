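"""Generate genomes carrying dated MITE amplification bursts with known truth.

The generative model: a master element bounded by perfect terminal inverted
repeats (TIRs), optionally with an internal deletion window that defines a
shorter derivative variant. Copies of either variant are aged from a
truncated-normal burst, mutated under the Jukes-Cantor model, inserted at
disjoint genomic positions flanked by a duplicated "TA" target site, and
reported as (optionally fragmented) homology hit records plus an exact
multiple alignment in master coordinates. Every downstream stage of the
pipeline can therefore be checked against this ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    GeneFeature,
    HitRecord,
    write_blast_tab,
    write_fasta,
    write_gene_bed,
    write_gff3,
    write_repeatmasker_out,
)

__all__ = [
    "MasterElement",
    "BurstModel",
    "CopyTruth",
    "SimulationResult",
    "reverse_complement",
    "expected_p",
    "make_master",
    "mutate_jc",
    "simulate_burst",
    "write_simulation",
]

TSD = "TA"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BASES = "ACGT"
_ACGT_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

# byte -> base index lookup (255 = not a plain ACGT base)
_IDX_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _IDX_LUT[_b] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, 4, size=n, dtype=np.uint8)
    return _ACGT_BYTES[idx].tobytes().decode("ascii")


def expected_p(rate_s: float, age: float) -> float:
    """Expected per-site difference after ``age`` years at rate ``rate_s``.

    ``p = (3/4) * (1 - exp(-(4/3) * rate_s * age))`` — the Jukes-Cantor
    forward map from elapsed substitutions to observable differences.
    """
    return 0.75 * (1.0 - math.exp(-(4.0 / 3.0) * rate_s * age))


@dataclass(frozen=True)
class MasterElement:
    """The ancestral element all simulated copies descend from.

    ``deletion_window`` (0-based half-open on the master) defines the
    segment missing from the derivative variant. ``segment_map`` labels
    the anatomical intervals (TIR5, mariner5, body, mariner3, TIR3).
    """

    id: str
    sequence: str
    tir_length: int
    deletion_window: tuple[int, int] | None
    segment_map: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        n = len(self.sequence)
        t = self.tir_length
        if t < 0 or 2 * t > n:
            raise ValueError(f"tir_length {t} infeasible for length {n}")
        if t > 0:
            head = self.sequence[:t].upper()
            tail = self.sequence[-t:].upper()
            if reverse_complement(tail) != head:
                raise ValueError("termini are not perfect inverted repeats")
        if self.deletion_window is not None:
            ds, de = self.deletion_window
            if not (0 <= ds < de <= n):
                raise ValueError(f"invalid deletion window ({ds}, {de}) for length {n}")
            if ds < max(1, t) or de > n - max(1, t):
                raise ValueError(
                    f"deletion window ({ds}, {de}) touches the element terminus/TIR"
                )
        prev_end = None
        for label, s, e in self.segment_map:
            if not (0 <= s < e <= n):
                raise ValueError(f"segment {label} interval ({s}, {e}) out of bounds")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"segment {label} overlaps the previous segment")
            prev_end = e

    @property
    def length(self) -> int:
        return len(self.sequence)

    def derivative_sequence(self) -> str:
        """Master sequence with the deletion window excised."""
        if self.deletion_window is None:
            raise ValueError("master has no deletion window")
        ds, de = self.deletion_window
        return self.sequence[:ds] + self.sequence[de:]


@dataclass(frozen=True)
class BurstModel:
    """Parameters of one amplification burst."""

    rate_s: float = 2.2e-9
    age_mean: float = 50e6
    age_sd: float = 2.5e6
    n_copies_per_variant: Mapping[str, int] = field(
        default_factory=lambda: {"full": 50, "deletion_derivative": 50}
    )
    fragmentation_prob: float = 0.0
    max_fragments: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_s <= 0:
            raise ValueError("rate_s must be > 0")
        if self.age_mean <= 0:
            raise ValueError("age_mean must be > 0")
        if self.age_sd < 0:
            raise ValueError("age_sd must be >= 0")
        if not 0.0 <= self.fragmentation_prob <= 1.0:
            raise ValueError("fragmentation_prob outside [0, 1]")
        if self.max_fragments < 1:
            raise ValueError("max_fragments must be >= 1")
        for variant, count in self.n_copies_per_variant.items():
            if variant not in ("full", "deletion_derivative"):
                raise ValueError(f"unknown variant {variant!r}")
            if count < 0:
                raise ValueError(f"negative copy count for {variant!r}")


@dataclass(frozen=True)
class CopyTruth:
    """Ground truth for one simulated insertion."""

    copy_id: str
    variant: str
    age: float
    expected_p: float
    realized_substitutions: int
    contig: str
    start: int
    end: int
    strand: str
    in_genic: bool


@dataclass
class SimulationResult:
    contig_id: str
    genome: str
    master: MasterElement
    truth: list[CopyTruth]
    hits: list[HitRecord]
    msa: list[tuple[str, str]]
    genes: list[GeneFeature]
    tsd: str = TSD


def make_master(
    length: int = 865,
    tir_length: int = 24,
    deletion_window: tuple[int, int] | None = (300, 561),
    seed: int = 0,
    element_id: str = "MITE_master",
) -> MasterElement:
    """Draw a random master element with perfect TIRs of exactly ``tir_length`` bp.

    The bases immediately inside each TIR are resampled so the inverted
    repeat does not extend past ``tir_length`` by chance, which makes the
    constructed TIR length exact and TIR detection deterministic.
    """
    span = 0 if deletion_window is None else deletion_window[1] - deletion_window[0]
    if length < 2 * tir_length + span:
        raise ValueError(
            f"length {length} cannot host two {tir_length} bp TIRs plus a "
            f"{span} bp deletion window"
        )
    rng = np.random.default_rng(seed)
    seq = list(_random_dna(rng, length))
    if tir_length > 0:
        seq[length - tir_length :] = list(
            reverse_complement("".join(seq[:tir_length]))
        )
        # break any chance extension of the inverted repeat just inside the TIRs
        margin = min(4, (length - 2 * tir_length) // 2)
        comp = dict(zip("ACGT", "TGCA"))
        for i in range(margin):
            a = tir_length + i
            b = length - tir_length - 1 - i
            if a >= b:
                break
            while comp[seq[b]] == seq[a]:
                seq[a] = _BASES[int(rng.integers(0, 4))]
    sequence = "".join(seq)

    segments: list[tuple[str, int, int]] = []

    def _add(label: str, s: int, e: int) -> None:
        if e > s:
            segments.append((label, s, e))

    if deletion_window is not None:
        ds, de = deletion_window
        _add("TIR5", 0, tir_length)
        _add("mariner5", tir_length, ds)
        _add("body", ds, de)
        _add("mariner3", de, length - tir_length)
        _add("TIR3", length - tir_length, length)
    else:
        _add("TIR5", 0, tir_length)
        _add("body", tir_length, length - tir_length)
        _add("TIR3", length - tir_length, length)

    return MasterElement(
        id=element_id,
        sequence=sequence,
        tir_length=tir_length,
        deletion_window=deletion_window,
        segment_map=tuple(segments),
    )


def mutate_jc(
    sequence: str, rate_s: float, age: float, rng: np.random.Generator
) -> tuple[str, int]:
    """Mutate each site independently under the Jukes-Cantor model.

    Each site is replaced with probability
    ``p = (3/4)(1 - exp(-(4/3) rate_s age))`` by a uniformly chosen
    different base. Returns the mutated sequence and the number of changed
    sites. Non-ACGT characters are left untouched.
    """
    value = rate_s * age
    if not math.isfinite(value):
        raise ValueError("rate_s * age must be finite")
    p = expected_p(rate_s, age)
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8).copy()
    idx = _IDX_LUT[arr]
    mutable = idx != 255
    hit = (rng.random(arr.size) < p) & mutable
    shift = rng.integers(1, 4, size=arr.size, dtype=np.uint8)
    new_idx = (idx.astype(np.int16) + shift) % 4
    arr[hit] = _ACGT_BYTES[new_idx[hit]]
    return arr.tobytes().decode("ascii"), int(hit.sum())


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Normal(mean, sd) truncated at zero, by rejection."""
    if size == 0:
        return np.empty(0)
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < 0
    return out


def _copy_query_intervals(master: MasterElement, variant: str) -> list[tuple[int, int]]:
    if variant == "full":
        return [(0, master.length)]
    ds, de = master.deletion_window  # type: ignore[misc]
    return [(0, ds), (de, master.length)]


def _fragment_intervals(
    intervals: list[tuple[int, int]],
    max_fragments: int,
    rng: np.random.Generator,
    min_fragment: int = 30,
    gap_low: int = 5,
    gap_high: int = 25,
) -> list[tuple[int, int]]:
    """Split the widest interval into collinear pieces separated by short gaps.

    Emulates an annotation tool fragmenting one contiguous diverged copy;
    the underlying DNA is untouched, only the reported intervals shrink.
    """
    extra = max_fragments - len(intervals)
    if extra < 1:
        return intervals
    widest = max(range(len(intervals)), key=lambda i: intervals[i][1] - intervals[i][0])
    qa, qb = intervals[widest]
    k = int(rng.integers(2, extra + 2))
    if qb - qa < k * (min_fragment + gap_high):
        return intervals
    edges = np.linspace(qa, qb, k + 1).astype(int)
    gaps = rng.integers(gap_low, gap_high + 1, size=k - 1)
    pieces: list[tuple[int, int]] = []
    for j in range(k):
        s = int(edges[j]) + (int(gaps[j - 1]) if j > 0 else 0)
        e = int(edges[j + 1])
        pieces.append((s, e))
    return intervals[:widest] + pieces + intervals[widest + 1 :]


def simulate_burst(
    master: MasterElement,
    burst: BurstModel,
    genome_length: int,
    gene_density: float = 0.2,
    rng: np.random.Generator | None = None,
    genic_flank_bp: int = 5000,
    contig_id: str = "contig_1",
) -> SimulationResult:
    """Simulate one genome carrying a dated amplification burst.

    Returns the genome sequence, per-copy ground truth, hit records in
    master coordinates, an exact MSA of copies padded to master
    coordinates (deletion as gaps), and synthetic gene features.
    """
    if rng is None:
        rng = np.random.default_rng(burst.seed)

    n_full = int(burst.n_copies_per_variant.get("full", 0))
    n_deriv = int(burst.n_copies_per_variant.get("deletion_derivative", 0))
    if n_deriv > 0 and master.deletion_window is None:
        raise ValueError("deletion_derivative copies requested but master has no deletion window")
    n = n_full + n_deriv

    if n > 0 and genome_length < 2 * n:
        raise ValueError(
            f"genome_length {genome_length} too small to host {n} disjoint copies; "
            "increase genome_length"
        )

    variants = ["full"] * n_full + ["deletion_derivative"] * n_deriv
    order = rng.permutation(n)
    variants = [variants[i] for i in order]

    positions = (
        np.sort(rng.choice(genome_length, size=n, replace=False)) if n else np.empty(0, int)
    )
    ages = _truncated_normal(rng, burst.age_mean, burst.age_sd, n)
    background = _random_dna(rng, genome_length)

    L = master.length
    ds, de = master.deletion_window if master.deletion_window else (L, L)
    del_span = de - ds
    tsd_len = len(TSD)

    parts: list[str] = []
    truth: list[CopyTruth] = []
    hits: list[HitRecord] = []
    msa: list[tuple[str, str]] = []
    prev = 0
    shift = 0  # total bases inserted so far

    def _to_local(q: int, variant: str) -> int:
        if variant == "full" or q <= ds:
            return q
        return q - del_span

    for i in range(n):
        variant = variants[i]
        pos = int(positions[i])
        base_seq = master.sequence if variant == "full" else master.derivative_sequence()
        mutated, nsub = mutate_jc(base_seq, burst.rate_s, ages[i], rng)
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = mutated if strand == "+" else reverse_complement(mutated)
        clen = len(mutated)

        elem_start = pos + shift + tsd_len
        elem_end = elem_start + clen

        parts.append(background[prev:pos])
        parts.append(TSD + inserted + TSD)
        prev = pos
        shift += clen + 2 * tsd_len

        copy_id = f"copy_{i:05d}"

        q_intervals = _copy_query_intervals(master, variant)
        if burst.fragmentation_prob > 0 and rng.random() < burst.fragmentation_prob:
            q_intervals = _fragment_intervals(q_intervals, burst.max_fragments, rng)

        for qa, qb in q_intervals:
            la, lb = _to_local(qa, variant), _to_local(qb, variant)
            seg_mut = mutated[la:lb]
            seg_master = master.sequence[qa:qb]
            matches = sum(a == b for a, b in zip(seg_mut, seg_master))
            span = lb - la
            if strand == "+":
                t0, t1 = elem_start + la, elem_start + lb
            else:
                t0, t1 = elem_start + clen - lb, elem_start + clen - la
            hits.append(
                HitRecord(
                    query_id=master.id,
                    target_id=contig_id,
                    query_start=qa,
                    query_end=qb,
                    target_start=t0,
                    target_end=t1,
                    strand=strand,
                    percent_identity=matches / span,
                    score=2.0 * matches - 3.0 * (span - matches),
                    evalue=1e-50,
                )
            )

        if variant == "full":
            row = mutated
        else:
            row = mutated[:ds] + "-" * del_span + mutated[ds:]
        msa.append((copy_id, row))

        truth.append(
            CopyTruth(
                copy_id=copy_id,
                variant=variant,
                age=float(ages[i]),
                expected_p=expected_p(burst.rate_s, float(ages[i])),
                realized_substitutions=nsub,
                contig=contig_id,
                start=elem_start,
                end=elem_end,
                strand=strand,
                in_genic=False,  # filled in below once genes are placed
            )
        )

    parts.append(background[prev:])
    genome = "".join(parts)
    assert len(genome) == genome_length + sum(t.end - t.start for t in truth) + 2 * tsd_len * n

    genes = _lay_down_genes(rng, contig_id, len(genome), gene_density)

    gene_level = [
        (g.start, g.end) for g in genes if g.feature_kind in ("gene", "lncRNA")
    ]
    final_truth: list[CopyTruth] = []
    for t in truth:
        genic = any(
            s - genic_flank_bp < t.end and t.start < e + genic_flank_bp
            for s, e in gene_level
        )
        final_truth.append(
            CopyTruth(
                t.copy_id,
                t.variant,
                t.age,
                t.expected_p,
                t.realized_substitutions,
                t.contig,
                t.start,
                t.end,
                t.strand,
                genic,
            )
        )

    return SimulationResult(
        contig_id=contig_id,
        genome=genome,
        master=master,
        truth=final_truth,
        hits=hits,
        msa=msa,
        genes=genes,
    )


def _lay_down_genes(
    rng: np.random.Generator,
    contig_id: str,
    genome_length: int,
    gene_density: float,
    lnc_fraction: float = 0.1,
) -> list[GeneFeature]:
    """Place non-overlapping synthetic genes covering ~``gene_density`` of the genome.

    Protein-coding genes get an mRNA child tiled as 5'UTR / CDS / 3'UTR
    (strand-aware); a fraction are emitted as lncRNA genes instead.
    """
    if gene_density <= 0 or genome_length < 3000:
        return []
    target_bp = gene_density * genome_length
    occupied: list[tuple[int, int]] = []
    feats: list[GeneFeature] = []
    covered = 0
    gid = 0
    attempts = 0
    while covered < target_bp and attempts < 20000:
        attempts += 1
        length = int(rng.integers(2000, 8001))
        if length >= genome_length:
            break
        start = int(rng.integers(0, genome_length - length))
        end = start + length
        if any(s < end and start < e for s, e in occupied):
            continue
        occupied.append((start, end))
        covered += length
        strand = "+" if rng.random() < 0.5 else "-"
        is_lnc = rng.random() < lnc_fraction
        if is_lnc:
            feats.append(
                GeneFeature(contig_id, start, end, strand, "lncRNA", f"lnc{gid}")
            )
        else:
            gene_id, mrna_id = f"g{gid}", f"m{gid}"
            feats.append(GeneFeature(contig_id, start, end, strand, "gene", gene_id))
            feats.append(
                GeneFeature(contig_id, start, end, strand, "mRNA", mrna_id, gene_id)
            )
            utr = max(50, length // 10)
            if strand == "-":
                five = (end - utr, end)
                three = (start, start + utr)
            else:
                five = (start, start + utr)
                three = (end - utr, end)
            cds = (start + utr, end - utr)
            feats.append(
                GeneFeature(contig_id, five[0], five[1], strand, "five_prime_UTR", f"{mrna_id}.utr5", mrna_id)
            )
            feats.append(
                GeneFeature(contig_id, cds[0], cds[1], strand, "CDS", f"{mrna_id}.cds", mrna_id)
            )
            feats.append(
                GeneFeature(contig_id, three[0], three[1], strand, "three_prime_UTR", f"{mrna_id}.utr3", mrna_id)
            )
        gid += 1
    feats.sort(key=lambda f: (f.start, f.end, f.id))
    return feats


def write_simulation(sim: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write all simulator outputs as plain-text files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fasta",
        "master": outdir / "master.fasta",
        "truth_bed": outdir / "truth.bed",
        "truth_tsv": outdir / "truth.tsv",
        "hits_blast": outdir / "hits.blast.tsv",
        "hits_rm": outdir / "hits.rm.out",
        "msa": outdir / "copies.aln.fasta",
        "genes_gff3": outdir / "genes.gff3",
        "genes_bed": outdir / "genes.bed",
    }
    write_fasta([(sim.contig_id, sim.genome)], paths["genome"])
    write_fasta([(sim.master.id, sim.master.sequence)], paths["master"])
    with open(paths["truth_bed"], "w") as fh:
        for t in sim.truth:
            fh.write(f"{t.contig}\t{t.start}\t{t.end}\t{t.copy_id}\t0\t{t.strand}\n")
    with open(paths["truth_tsv"], "w") as fh:
        fh.write(
            "copy_id\tvariant\tage\texpected_p\trealized_substitutions\t"
            "contig\tstart\tend\tstrand\tin_genic\n"
        )
        for t in sim.truth:
            fh.write(
                f"{t.copy_id}\t{t.variant}\t{t.age:.1f}\t{t.expected_p:.6f}\t"
                f"{t.realized_substitutions}\t{t.contig}\t{t.start}\t{t.end}\t"
                f"{t.strand}\t{int(t.in_genic)}\n"
            )
    write_blast_tab(sim.hits, paths["hits_blast"])
    write_repeatmasker_out(
        sim.hits,
        paths["hits_rm"],
        query_lengths={sim.master.id: sim.master.length},
        target_lengths={sim.contig_id: len(sim.genome)},
    )
    write_fasta(sim.msa, paths["msa"])
    write_gff3(sim.genes, paths["genes_gff3"])
    write_gene_bed(
        [g for g in sim.genes if g.feature_kind in ("gene", "lncRNA")],
        paths["genes_bed"],
    )
    return paths
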