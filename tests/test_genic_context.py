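import numpy as np
import pytest

from _oracles import chi2_hand
from mitewave.genic_context import (
    genic_overlap,
    independence_test,
    posthoc_pairwise,
    transcript_context,
)
from mitewave.io_formats import GeneFeature


def _gene(start, end, contig="chr1", gid="g1"):
    return GeneFeature(contig, start, end, "+", "gene", gid)


class TestGenicOverlap:
    def test_single_shared_base_at_flank_boundary(self):
        # gene 10000..20000, flank 5000: extended gene starts at 5000;
        # copy 4999..5001 shares one base
        row = genic_overlap([("chr1", 4999, 5001)], [_gene(10000, 20000)], flank_bp=5000)
        assert row.n_genic == 1
        assert row.n_flank_only == 1

    def test_no_shared_base_just_outside(self):
        row = genic_overlap([("chr1", 4998, 5000)], [_gene(10000, 20000)], flank_bp=5000)
        assert row.n_genic == 0

    def test_flank_only_downstream(self):
        row = genic_overlap([("chr1", 24999, 25100)], [_gene(10000, 20000)], flank_bp=5000)
        assert row.n_genic == 1
        assert row.n_flank_only == 1
        assert row.n_gene_body == 0

    def test_gene_body(self):
        row = genic_overlap([("chr1", 15000, 15100)], [_gene(10000, 20000)], flank_bp=5000)
        assert row.n_gene_body == 1
        assert row.n_flank_only == 0

    def test_unknown_contig_counts_non_genic(self, caplog):
        with caplog.at_level("WARNING"):
            row = genic_overlap([("chrX", 0, 100)], [_gene(10000, 20000)], flank_bp=5000)
        assert row.n_genic == 0
        assert "chrX" in caplog.text

    def test_simulator_truth_fraction_exact(self, mixed_burst):
        copies = [(t.contig, t.start, t.end) for t in mixed_burst.truth]
        row = genic_overlap(copies, mixed_burst.genes, flank_bp=5000, species="sim")
        truth_genic = sum(t.in_genic for t in mixed_burst.truth)
        assert row.n_genic == truth_genic
        assert row.percent_genic == pytest.approx(100 * truth_genic / len(copies))

    def test_percent_invariant(self):
        row = genic_overlap(
            [("chr1", 15000, 15100), ("chr1", 500_000, 500_100)],
            [_gene(10000, 20000)],
            flank_bp=5000,
        )
        assert row.n_genic <= row.n_total
        assert row.n_gene_body + row.n_flank_only == row.n_genic
        assert row.percent_genic == 50.0


class TestIndependenceTest:
    def test_uniform_table(self):
        chi2, df, p = independence_test([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_oracle_value(self):
        # [[30,70],[50,50]] -> chi2 = 8.3333, df = 1
        chi2, df, p = independence_test([[30, 70], [50, 50]])
        assert chi2 == pytest.approx(8.3333, abs=1e-4)
        assert df == 1
        oracle = chi2_hand([[30, 70], [50, 50]])
        assert chi2 == pytest.approx(oracle[0], abs=1e-10)
        assert p == pytest.approx(oracle[2], abs=1e-12)

    def test_zero_row_sum_raises(self):
        with pytest.raises(ValueError):
            independence_test([[0, 0], [10, 10]])

    def test_needs_two_rows(self):
        with pytest.raises(ValueError):
            independence_test([[10, 10]])

    def test_type_one_error_calibration(self):
        # equal-proportion species: rejection rate at alpha = 0.05 within
        # binomial 3 s.e. over 200 replicates
        rng = np.random.default_rng(2024)
        n, p_genic, reps = 300, 0.4, 200
        rejections = 0
        for _ in range(reps):
            table = []
            for _ in range(3):
                genic = rng.binomial(n, p_genic)
                table.append([genic, n - genic])
            _, _, p = independence_test(table)
            rejections += p < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) < 3 * se


class TestPosthocPairwise:
    def test_identical_rows_not_significant(self):
        table = [[40, 60]] * 4
        results = posthoc_pairwise(table, alpha=0.01)
        assert not any(r.significant for r in results)

    def test_comparison_count_k6(self):
        table = [[40, 60]] * 6
        results = posthoc_pairwise(table)
        assert len(results) == 15

    def test_outlier_species_significant_against_all(self):
        # one species at 25% genic vs five at 41%, n = 500 each
        table = [[125, 375]] + [[205, 295]] * 5
        labels = ["outlier"] + [f"sp{i}" for i in range(5)]
        results = posthoc_pairwise(table, labels=labels, alpha=0.01)
        involving = [r for r in results if "outlier" in (r.species_i, r.species_j)]
        assert len(involving) == 5
        assert all(r.significant for r in involving)
        others = [r for r in results if "outlier" not in (r.species_i, r.species_j)]
        assert not any(r.significant for r in others)

    def test_bonferroni_monotonicity(self):
        rng = np.random.default_rng(5)
        table = rng.integers(5, 200, size=(5, 2)).tolist()
        strict = {
            (r.species_i, r.species_j)
            for r in posthoc_pairwise(table, alpha=0.001)
            if r.significant
        }
        loose = {
            (r.species_i, r.species_j)
            for r in posthoc_pairwise(table, alpha=0.01)
            if r.significant
        }
        assert strict <= loose

    def test_k_below_three_raises(self):
        with pytest.raises(ValueError):
            posthoc_pairwise([[10, 10], [10, 10]])


class TestTranscriptContext:
    def _features(self):
        return [
            GeneFeature("chr1", 1000, 9000, "+", "gene", "g1"),
            GeneFeature("chr1", 1000, 9000, "+", "mRNA", "m1", "g1"),
            GeneFeature("chr1", 1000, 2000, "+", "five_prime_UTR", "m1.u5", "m1"),
            GeneFeature("chr1", 2000, 8000, "+", "CDS", "m1.cds", "m1"),
            GeneFeature("chr1", 8000, 9000, "+", "three_prime_UTR", "m1.u3", "m1"),
            GeneFeature("chr1", 20000, 25000, "+", "lncRNA", "l1"),
        ]

    def test_copy_inside_cds(self):
        counts = transcript_context([("chr1", 3000, 3500)], self._features())
        assert counts["CDS"] == 1
        assert counts["mRNA_total"] == 1

    def test_junction_priority_cds(self):
        # spanning the 5'UTR/CDS junction counts as CDS
        counts = transcript_context([("chr1", 1900, 2100)], self._features())
        assert counts["CDS"] == 1
        assert counts["five_prime_UTR"] == 0

    def test_utr_hits(self):
        counts = transcript_context(
            [("chr1", 1100, 1200), ("chr1", 8100, 8200)], self._features()
        )
        assert counts["five_prime_UTR"] == 1
        assert counts["three_prime_UTR"] == 1

    def test_lncrna_counted_separately(self):
        counts = transcript_context([("chr1", 21000, 21100)], self._features())
        assert counts["lncRNA"] == 1
        assert counts["mRNA_total"] == 0

    def test_simulator_counts_match_bruteforce(self, mixed_burst):
        copies = [(t.contig, t.start, t.end) for t in mixed_burst.truth]
        counts = transcript_context(copies, mixed_burst.genes)
        # independent brute-force classification
        feats = mixed_burst.genes
        mrnas = [f for f in feats if f.feature_kind == "mRNA"]
        kids = {}
        for f in feats:
            if f.parent_id:
                kids.setdefault(f.parent_id, []).append(f)
        expect = {"CDS": 0, "five_prime_UTR": 0, "three_prime_UTR": 0, "mRNA_total": 0}
        for contig, cs, ce in copies:
            over = [
                k.feature_kind
                for m in mrnas
                if m.start < ce and cs < m.end
                for k in kids.get(m.id, [])
                if k.start < ce and cs < k.end
            ]
            if any(m.start < ce and cs < m.end for m in mrnas):
                expect["mRNA_total"] += 1
                for kind in ("CDS", "five_prime_UTR", "three_prime_UTR"):
                    if kind in over:
                        expect[kind] += 1
                        break
        for key, value in expect.items():
            assert counts[key] == value


def test_exhaustive_2x2_oracle_small():
    # spot version of the acceptance sweep: all 2x2 tables with margins <= 8
    from itertools import product

    for a, b, c, d in product(range(9), repeat=4):
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        if max(a + b, c + d, a + c, b + d) > 8:
            continue
        chi2, df, p = independence_test([[a, b], [c, d]])
        o_chi2, o_df, o_p = chi2_hand([[a, b], [c, d]])
        assert chi2 == pytest.approx(o_chi2, abs=1e-10)
        assert df == o_df
        assert p == pytest.approx(o_p, abs=1e-12)
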