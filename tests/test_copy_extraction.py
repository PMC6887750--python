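import numpy as np
import pytest

from _oracles import min_chain_partition
from mitewave.copy_extraction import (
    assign_variant,
    assign_variants,
    filter_by_coverage,
    merge_fragments,
)
from mitewave.io_formats import HitRecord


def _hit(qs, qe, ts, te, strand="+", qid="MER6", tid="chr1"):
    return HitRecord(qid, tid, qs, qe, ts, te, strand, 0.9)


class TestMergeFragments:
    def test_two_collinear_fragments_chain(self):
        # target 100..400 (query 0..300) and 450..700 (query 320..570), gap 50
        hits = [_hit(0, 300, 100, 400), _hit(320, 570, 450, 700)]
        copies = merge_fragments(hits, query_length=865, max_gap_bp=150)
        assert len(copies) == 1
        c = copies[0]
        assert (c.start, c.end) == (100, 700)
        # coverage is the union of query intervals: 300 + 250 bases
        assert c.query_coverage == pytest.approx(550 / 865)
        assert len(c.fragments) == 2

    def test_reversed_query_order_on_plus_strand_not_chained(self):
        hits = [_hit(320, 570, 100, 400), _hit(0, 300, 450, 700)]
        copies = merge_fragments(hits, query_length=865, max_gap_bp=150)
        assert len(copies) == 2

    def test_minus_strand_collinearity(self):
        # on "-" the query order is reversed relative to genomic order
        hits = [
            _hit(320, 570, 100, 350, strand="-"),
            _hit(0, 300, 400, 700, strand="-"),
        ]
        copies = merge_fragments(hits, query_length=865, max_gap_bp=150)
        assert len(copies) == 1
        assert copies[0].strand == "-"

    def test_single_full_length_hit(self):
        copies = merge_fragments([_hit(0, 865, 1000, 1865)], query_length=865)
        assert len(copies) == 1
        assert copies[0].query_coverage == pytest.approx(1.0)

    def test_gap_beyond_max_not_chained(self):
        hits = [_hit(0, 300, 100, 400), _hit(320, 570, 1000, 1250)]
        copies = merge_fragments(hits, query_length=865, max_gap_bp=150)
        assert len(copies) == 2

    def test_every_hit_in_exactly_one_copy(self, fragmented_burst):
        copies = merge_fragments(fragmented_burst.hits, query_length=865)
        assert sum(len(c.fragments) for c in copies) == len(fragmented_burst.hits)
        seen = set()
        for c in copies:
            for f in c.fragments:
                key = (f.target_start, f.target_end, f.query_start)
                assert key not in seen
                seen.add(key)

    def test_defragmentation_recovery(self, fragmented_burst):
        # >= 95% of fragmented copies reassembled to their true interval +-5 bp
        copies = merge_fragments(fragmented_burst.hits, query_length=865)
        truth = {(t.start, t.end) for t in fragmented_burst.truth}
        matched = 0
        for c in copies:
            if any(abs(c.start - s) <= 5 and abs(c.end - e) <= 5 for s, e in truth):
                matched += 1
        assert len(copies) >= len(fragmented_burst.truth)
        assert matched >= 0.95 * len(fragmented_burst.truth)

    def test_greedy_matches_exhaustive_oracle(self):
        # random fragmented-copy instances (disjoint copies, collinear
        # non-overlapping fragments): greedy chaining must reach the
        # oracle's minimum chain count
        rng = np.random.default_rng(42)
        for trial in range(60):
            hits = []
            cursor = 0
            n_copies = int(rng.integers(1, 4))
            for _ in range(n_copies):
                cursor += int(rng.integers(50, 700))
                n_frag = int(rng.integers(1, 4))
                q = int(rng.integers(0, 50))
                t = cursor
                for _ in range(n_frag):
                    span = int(rng.integers(40, 200))
                    hits.append(_hit(q, q + span, t, t + span))
                    gap = int(rng.integers(5, 120))
                    q += span + int(rng.integers(0, 40))
                    t += span + gap
                    if q + 40 > 865:
                        break
                cursor = t
            copies = merge_fragments(hits, query_length=865)
            assert len(copies) == min_chain_partition(hits)

    def test_interleaved_instances_against_oracle(self):
        # adversarial-ish: fragments of two nearby copies
        rng = np.random.default_rng(7)
        for trial in range(40):
            hits = []
            base = 0
            for copy in range(2):
                q, t = 0, base
                for _ in range(int(rng.integers(1, 4))):
                    span = int(rng.integers(30, 120))
                    hits.append(_hit(q, q + span, t, t + span))
                    q += span + int(rng.integers(0, 30))
                    t += span + int(rng.integers(5, 80))
                base += int(rng.integers(200, 600))
            copies = merge_fragments(hits, query_length=865)
            assert len(copies) == min_chain_partition(hits)


class TestFilterByCoverage:
    def _copy_with_coverage(self, qspan):
        hits = [_hit(0, qspan, 0, qspan)]
        (c,) = merge_fragments(hits, query_length=865)
        return c

    def test_coverage_500_of_865_retained(self):
        c = self._copy_with_coverage(500)
        assert c.query_coverage == pytest.approx(500 / 865)
        assert filter_by_coverage([c]) == [c]

    def test_coverage_400_of_865_removed(self):
        c = self._copy_with_coverage(400)
        assert filter_by_coverage([c]) == []

    def test_exactly_half_removed_strict(self):
        hits = [_hit(0, 100, 0, 100)]
        (c,) = merge_fragments(hits, query_length=200)
        assert c.query_coverage == 0.5
        assert filter_by_coverage([c], min_fraction=0.5) == []


class TestAssignVariant:
    def test_full_copy(self, master865):
        (c,) = merge_fragments([_hit(0, 865, 0, 865)], query_length=865)
        assert assign_variant(c, master865) == "full"

    def test_deletion_derivative(self, master865):
        hits = [_hit(0, 300, 0, 300), _hit(561, 865, 300, 604)]
        (c,) = merge_fragments(hits, query_length=865)
        assert assign_variant(c, master865) == "deletion_derivative"

    def test_ambiguous_half_window(self, master865):
        # covering 0..430 only: window (300, 561) covered 130/261 = 0.498
        (c,) = merge_fragments([_hit(0, 430, 0, 430)], query_length=865)
        assert assign_variant(c, master865) == "ambiguous"

    def test_variant_assignment_matches_truth(self, fragmented_burst, master865):
        copies = merge_fragments(fragmented_burst.hits, query_length=865)
        copies = filter_by_coverage(copies)
        copies = assign_variants(copies, master865)
        truth = {t.start: t.variant for t in fragmented_burst.truth}
        checked = 0
        for c in copies:
            for s, variant in truth.items():
                if abs(c.start - s) <= 5 and c.variant != "ambiguous":
                    assert c.variant == variant
                    checked += 1
                    break
        assert checked >= 0.9 * len(fragmented_burst.truth)

    def test_no_deletion_window_raises(self):
        from mitewave.synthetic_data import make_master

        m = make_master(length=300, tir_length=10, deletion_window=None, seed=1)
        (c,) = merge_fragments([_hit(0, 300, 0, 300, qid=m.id)], query_length=300)
        with pytest.raises(ValueError, match="deletion window"):
            assign_variant(c, m)
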