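# mitewave

Archaeology of MITE (miniature inverted-repeat transposable element)
repeat families, driven by a synthetic amplification-burst simulator so
every stage can be verified against known ground truth — no downloads or
external search tools required.

The pipeline covers:

- **io_formats** — readers/writers for FASTA, BLAST tabular (outfmt 6),
  RepeatMasker `.out`, BED4+/GFF3 gene annotations and square PHYLIP
  distance matrices. All coordinates are normalised to 0-based half-open
  intervals; percent identity is a fraction in [0, 1].
- **synthetic_data** — generates a genome carrying a dated burst of a
  master element (default 865 bp, 24 bp TIRs) and its 261 bp internal
  deletion derivative: truncated-normal insertion ages, Jukes–Cantor
  mutation, "TA" target-site duplications, optional hit-record
  fragmentation, synthetic gene annotations, and an exact MSA of copies
  in master coordinates.
- **coverage_profile** — per-position query coverage from hit records and
  detection of low-coverage "drop" windows diagnostic of deletion
  derivatives.
- **copy_extraction** — greedy defragmentation of collinear hit fragments
  into copies, the strict >50% query-coverage filter, and variant
  assignment from deletion-window coverage.
- **consensus_divergence** — majority-rule consensus from an MSA and
  per-copy Jukes–Cantor divergence landscapes
  (`d = -(3/4) ln(1 - (4/3) p)`, pairwise deletion for gaps/N).
- **activity_dating** — substitution-rate calibration and event dating
  via `T = D/s` (rate from mean divergence over a known split time; wave
  end from the youngest-copy divergence floor).
- **genic_context** — copies within genes ± flanking regions (default
  5000 bp), chi-square independence across species, Bonferroni-corrected
  pairwise post-hoc tests, and transcript sub-feature classification
  (CDS > 5'UTR > 3'UTR priority; lncRNA counted separately).
- **composite_structure** — Smith–Waterman local alignment with affine
  gaps, iterative homology-segment tiling of an element against candidate
  parental sequences, and terminal-inverted-repeat detection.
- **pipeline** / **cli** — YAML-configured orchestration with a
  deterministic, seed-stamped report directory.

## Test

```bash
python -m pytest -q tests/
```

The suite includes independent oracles (brute-force alignment DP, hand
chi-square formula, exhaustive chain-partition search), property tests
(hypothesis) and an acceptance suite (`tests/test_acceptance.py`) that
checks rate calibration, wave dating, oracle equivalences, simulator
parameter recovery, structure recovery and the filter/merge contract.

## CLI

```bash
mitewave run --config run.yaml --seed 42          # full pipeline -> report dir
mitewave simulate --seed 3 --out sim/             # burst genome + ground truth
mitewave coverage --hits sim/hits.blast.tsv --query-length 865 --out cov
mitewave extract --hits sim/hits.rm.out --dialect rm --query-length 865 --out ext
mitewave divergence --msa sim/copies.aln.fasta --out div
mitewave date --divergence div.divergence.tsv --split 96e6 --rate 2.2e-9 --out dating.tsv
mitewave context --copies ext.copies.bed --genes sim/genes.gff3 --flank 5000 --out ctx.tsv
mitewave dissect --mite master.fasta --subjects parents.fasta --out dis
mitewave convert --hits g.out --from rm --out hits.tsv
mitewave distances --msa copies.aln.fasta --out d.phy
```

All run parameters (copy numbers, rates, ages, thresholds, split times)
live in the YAML config; every report file records the seed in its
header and identical seeds give byte-identical reports.

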