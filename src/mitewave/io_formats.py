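"""Readers and writers for the external formats the pipeline touches.

Every reader normalises coordinates to one internal convention: 0-based
half-open intervals with ``start < end``. Minus-strand alignments keep
``target_start < target_end`` and carry a ``strand`` flag. Percent identity
is stored as a fraction in ``[0, 1]`` everywhere and rendered as a
percentage only in reports.

Supported formats: FASTA, 12-column BLAST tabular (outfmt 6),
RepeatMasker ``.out``, BED4+, GFF3 and square PHYLIP distance matrices.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

log = logging.getLogger(__name__)

__all__ = [
    "HitRecord",
    "GeneFeature",
    "FEATURE_KINDS",
    "read_fasta",
    "write_fasta",
    "read_blast_tab",
    "write_blast_tab",
    "read_repeatmasker_out",
    "write_repeatmasker_out",
    "read_gene_annotation",
    "write_gene_bed",
    "write_gff3",
    "write_phylip_distances",
    "read_phylip_distances",
]

FEATURE_KINDS = frozenset(
    {"gene", "mRNA", "five_prime_UTR", "CDS", "three_prime_UTR", "lncRNA"}
)

#: GFF3 "type" column spellings accepted for each internal feature kind.
_GFF_KIND_MAP = {
    "gene": "gene",
    "mRNA": "mRNA",
    "five_prime_UTR": "five_prime_UTR",
    "CDS": "CDS",
    "three_prime_UTR": "three_prime_UTR",
    "lncRNA": "lncRNA",
    "lnc_RNA": "lncRNA",
}


@dataclass(frozen=True)
class HitRecord:
    """One local homology alignment between a query element and a genomic target.

    Coordinates are 0-based half-open on both the query element and the
    target contig; a minus-strand hit keeps ``target_start < target_end``
    and sets ``strand`` to ``"-"``.
    """

    query_id: str
    target_id: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str
    percent_identity: float
    score: float = 0.0
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if self.query_start >= self.query_end:
            raise ValueError(
                f"hit {self.query_id}->{self.target_id}: query interval "
                f"[{self.query_start}, {self.query_end}) is empty"
            )
        if self.target_start >= self.target_end:
            raise ValueError(
                f"hit {self.query_id}->{self.target_id}: target interval "
                f"[{self.target_start}, {self.target_end}) is empty"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not 0.0 <= self.percent_identity <= 1.0:
            raise ValueError(
                f"percent_identity {self.percent_identity} outside [0, 1]"
            )
        if self.evalue < 0:
            raise ValueError(f"negative evalue {self.evalue}")

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start


@dataclass(frozen=True)
class GeneFeature:
    """A gene-annotation interval (gene, transcript or transcript sub-feature)."""

    contig: str
    start: int
    end: int
    strand: str
    feature_kind: str
    id: str
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"feature {self.id}: interval [{self.start}, {self.end}) is empty"
            )
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]``.

    Case is preserved (soft-masked bases are accepted); duplicate record
    ids raise. An empty file yields an empty list.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)


def read_blast_tab(path: str | Path) -> list[HitRecord]:
    """Parse 12-column BLAST tabular output into normalised :class:`HitRecord` s.

    Input coordinates are 1-based inclusive; ``sstart > send`` encodes a
    minus-strand hit. ``pident`` is divided by 100 on read.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric field ({exc})") from exc
            if qstart >= qend:
                raise ValueError(
                    f"line {lineno}: zero-length query interval after conversion "
                    f"(qstart={qstart}, qend={qend})"
                )
            if sstart == send:
                raise ValueError(
                    f"line {lineno}: zero-length target interval (sstart == send == {sstart})"
                )
            strand = "+" if sstart < send else "-"
            t0, t1 = (sstart - 1, send) if strand == "+" else (send - 1, sstart)
            hits.append(
                HitRecord(
                    query_id=fields[0],
                    target_id=fields[1],
                    query_start=qstart - 1,
                    query_end=qend,
                    target_start=t0,
                    target_end=t1,
                    strand=strand,
                    percent_identity=pident / 100.0,
                    score=bitscore,
                    evalue=evalue,
                )
            )
    return hits


def write_blast_tab(hits: Iterable[HitRecord], path: str | Path) -> None:
    """Serialise hits in the 12-column BLAST tabular dialect (inverse of the reader)."""
    with open(path, "w") as fh:
        for h in hits:
            length = h.query_span
            mismatch = int(round(length * (1.0 - h.percent_identity)))
            if h.strand == "+":
                sstart, send = h.target_start + 1, h.target_end
            else:
                sstart, send = h.target_end, h.target_start + 1
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.target_id,
                        f"{h.percent_identity * 100:.2f}",
                        str(length),
                        str(mismatch),
                        "0",
                        str(h.query_start + 1),
                        str(h.query_end),
                        str(sstart),
                        str(send),
                        f"{h.evalue:.2g}",
                        f"{h.score:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# RepeatMasker .out

_PAREN = re.compile(r"^\((\d+)\)$")

_RM_HEADER = (
    "   SW   perc perc perc  query     position in query            matching"
    "  repeat          position in repeat\n"
    "score   div. del. ins.  sequence  begin end          (left)    repeat"
    "  class/family    begin end (left)  ID\n"
    "\n"
)


def read_repeatmasker_out(path: str | Path) -> list[HitRecord]:
    """Parse a RepeatMasker ``.out`` file into normalised :class:`HitRecord` s.

    The repeat-consensus coordinates become the query interval and the
    genomic coordinates the target interval; strand ``C`` maps to ``-``
    (where the parenthesized repeat-left field swaps position). The
    divergence column is stored as ``percent_identity = 1 - div/100``.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if not fields[0].replace(".", "").isdigit():
                # header lines ("SW score ..." banner)
                continue
            if len(fields) < 14:
                raise ValueError(f"line {lineno}: expected >= 14 whitespace-separated fields")
            try:
                score = float(fields[0])
                div = float(fields[1])
                tname = fields[4]
                tbegin, tend = int(fields[5]), int(fields[6])
                strand_raw = fields[8]
                rep = fields[9]
                if strand_raw == "+":
                    left_field = fields[13]
                    rbegin, rend = int(fields[11]), int(fields[12])
                elif strand_raw == "C":
                    left_field = fields[11]
                    rend, rbegin = int(fields[12]), int(fields[13])
                else:
                    raise ValueError(f"line {lineno}: invalid strand field {strand_raw!r}")
            except ValueError as exc:
                if "line" in str(exc):
                    raise
                raise ValueError(f"line {lineno}: non-numeric coordinate field ({exc})") from exc
            if not _PAREN.match(left_field):
                raise ValueError(
                    f"line {lineno}: malformed parenthesized repeat-left field {left_field!r}"
                )
            hits.append(
                HitRecord(
                    query_id=rep,
                    target_id=tname,
                    query_start=rbegin - 1,
                    query_end=rend,
                    target_start=tbegin - 1,
                    target_end=tend,
                    strand="+" if strand_raw == "+" else "-",
                    percent_identity=1.0 - div / 100.0,
                    score=score,
                )
            )
    return hits


def write_repeatmasker_out(
    hits: Iterable[HitRecord],
    path: str | Path,
    query_lengths: Mapping[str, int] | None = None,
    target_lengths: Mapping[str, int] | None = None,
) -> None:
    """Serialise hits in the RepeatMasker ``.out`` dialect (inverse of the reader)."""
    query_lengths = query_lengths or {}
    target_lengths = target_lengths or {}
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, h in enumerate(hits, 1):
            div = (1.0 - h.percent_identity) * 100.0
            tleft = target_lengths.get(h.target_id, h.target_end) - h.target_end
            qleft = query_lengths.get(h.query_id, h.query_end) - h.query_end
            if h.strand == "+":
                rep_cols = [str(h.query_start + 1), str(h.query_end), f"({qleft})"]
                strand = "+"
            else:
                rep_cols = [f"({qleft})", str(h.query_end), str(h.query_start + 1)]
                strand = "C"
            fh.write(
                " ".join(
                    [
                        f"{h.score:.0f}",
                        f"{div:.1f}",
                        "0.0",
                        "0.0",
                        h.target_id,
                        str(h.target_start + 1),
                        str(h.target_end),
                        f"({tleft})",
                        strand,
                        h.query_id,
                        "DNA/TcMar",
                        *rep_cols,
                        str(i),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Gene annotations (BED4+ / GFF3)


def _parse_gff_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in field.split(";"):
        item = item.strip()
        if not item or "=" not in item:
            continue
        key, value = item.split("=", 1)
        attrs[key] = value
    return attrs


def read_gene_annotation(path: str | Path, dialect: str) -> list[GeneFeature]:
    """Read gene features from BED (0-based half-open) or GFF3 (1-based inclusive).

    GFF3 ``Parent`` attributes are captured as ``parent_id``; features of
    unknown kinds are skipped and their count logged.
    """
    if dialect not in ("bed", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    feats: list[GeneFeature] = []
    skipped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if dialect == "bed":
                if len(fields) < 3:
                    raise ValueError(f"line {lineno}: BED needs >= 3 columns")
                contig, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else f"{contig}:{start}-{end}"
                strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
                feats.append(GeneFeature(contig, start, end, strand, "gene", name))
            else:
                if len(fields) != 9:
                    raise ValueError(f"line {lineno}: GFF3 needs 9 columns")
                kind = _GFF_KIND_MAP.get(fields[2])
                if kind is None:
                    skipped += 1
                    continue
                start1, end1 = int(fields[3]), int(fields[4])
                if start1 > end1:
                    raise ValueError(f"line {lineno}: start > end ({start1} > {end1})")
                strand = fields[6] if fields[6] in "+-" else "."
                attrs = _parse_gff_attributes(fields[8])
                fid = attrs.get("ID", f"{fields[0]}:{start1}-{end1}:{kind}")
                feats.append(
                    GeneFeature(
                        contig=fields[0],
                        start=start1 - 1,
                        end=end1,
                        strand=strand,
                        feature_kind=kind,
                        id=fid,
                        parent_id=attrs.get("Parent"),
                    )
                )
    if skipped:
        log.warning("%d features of unknown kind skipped in %s", skipped, path)
    return feats


def write_gene_bed(features: Iterable[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\t{f.id}\t0\t{f.strand}\n")


def write_gff3(features: Iterable[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.id}"
            if f.parent_id is not None:
                attrs += f";Parent={f.parent_id}"
            fh.write(
                "\t".join(
                    [
                        f.contig,
                        "mitewave",
                        "lnc_RNA" if f.feature_kind == "lncRNA" else f.feature_kind,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Square PHYLIP distance matrices


def _uniquify_names(names: Sequence[str]) -> list[str]:
    short: list[str] = []
    seen: set[str] = set()
    for name in names:
        cand = name[:10]
        if cand in seen:
            i = 1
            while True:
                suffix = f"_{i}"
                cand = name[: 10 - len(suffix)] + suffix
                if cand not in seen:
                    break
                i += 1
        seen.add(cand)
        short.append(cand)
    return short


def write_phylip_distances(
    names: Sequence[str], matrix: np.ndarray, path: str | Path
) -> list[str]:
    """Write a square PHYLIP distance matrix.

    Names are truncated/uniquified to 10 characters; a ``<path>.names.tsv``
    sidecar maps short names back to full names. Returns the short names.
    """
    m = np.asarray(matrix, dtype=float)
    n = len(names)
    if m.shape != (n, n):
        raise ValueError(f"matrix shape {m.shape} does not match {n} names")
    if np.abs(np.diag(m)).max(initial=0.0) > 1e-9:
        raise ValueError("distance matrix diagonal is not zero")
    if np.abs(m - m.T).max(initial=0.0) > 1e-9:
        raise ValueError("distance matrix asymmetry beyond 1e-9")
    short = _uniquify_names(names)
    with open(path, "w") as fh:
        fh.write(f"{n}\n")
        for i in range(n):
            row = " ".join(f"{v:.9f}" for v in m[i])
            fh.write(f"{short[i]:<10s} {row}\n")
    with open(str(path) + ".names.tsv", "w") as fh:
        fh.write("short_name\tfull_name\n")
        for s, full in zip(short, names):
            fh.write(f"{s}\t{full}\n")
    return short


def read_phylip_distances(path: str | Path) -> tuple[list[str], np.ndarray]:
    with open(path) as fh:
        n = int(fh.readline().split()[0])
        names: list[str] = []
        rows: list[list[float]] = []
        for _ in range(n):
            fields = fh.readline().split()
            names.append(fields[0])
            rows.append([float(v) for v in fields[1:]])
    m = np.asarray(rows, dtype=float)
    if m.shape != (n, n):
        raise ValueError(f"malformed PHYLIP matrix: shape {m.shape}, expected ({n}, {n})")
    return names, m


def file_sha256(path: str | Path) -> str:
    """Hex digest of a file's contents (used in run manifests)."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
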