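import math

import numpy as np
import pytest

from mitewave.consensus_divergence import p_distance
from mitewave.synthetic_data import (
    BurstModel,
    expected_p,
    make_master,
    mutate_jc,
    reverse_complement,
    simulate_burst,
    write_simulation,
)

TSD_LEN = 2


class TestMakeMaster:
    def test_default_geometry(self, master865):
        m = master865
        assert m.length == 865
        assert m.tir_length == 24
        head = m.sequence[:24]
        tail = m.sequence[-24:]
        assert reverse_complement(tail) == head

    def test_zero_tir_allowed(self):
        m = make_master(length=200, tir_length=0, deletion_window=(50, 100), seed=1)
        assert m.tir_length == 0

    def test_deletion_window_touching_terminus_raises(self):
        with pytest.raises(ValueError, match="terminus"):
            make_master(length=200, tir_length=10, deletion_window=(0, 10), seed=1)

    def test_infeasible_geometry_raises(self):
        with pytest.raises(ValueError):
            make_master(length=100, tir_length=30, deletion_window=(35, 80), seed=1)

    def test_segment_map_tiles_element(self, master865):
        covered = sum(e - s for _, s, e in master865.segment_map)
        assert covered == master865.length
        labels = [lab for lab, _, _ in master865.segment_map]
        assert labels == ["TIR5", "mariner5", "body", "mariner3", "TIR3"]

    def test_derivative_excises_window(self, master865):
        deriv = master865.derivative_sequence()
        assert len(deriv) == 865 - 261
        assert deriv == master865.sequence[:300] + master865.sequence[561:]


class TestMutateJc:
    def test_age_zero_identity(self):
        rng = np.random.default_rng(0)
        seq = "ACGT" * 100
        out, count = mutate_jc(seq, 2.2e-9, 0.0, rng)
        assert out == seq
        assert count == 0

    def test_expected_p_closed_form(self):
        # rate*age = 0.12 -> p = (3/4)(1 - e^{-0.16}) = 0.110886...
        p = expected_p(2.2e-9, 0.12 / 2.2e-9)
        assert p == pytest.approx(0.75 * (1 - math.exp(-0.16)), abs=1e-12)
        assert p == pytest.approx(0.1109, abs=5e-5)

    def test_binomial_sampling_oracle(self):
        # 10,000-site sequence, rate*age = 0.12, 50 seeds:
        # mean observed p within 3 s.e. of the closed form.
        n_sites, n_seeds = 10_000, 50
        p_true = 0.75 * (1 - math.exp(-0.16))
        seq = "".join("ACGT"[i] for i in np.random.default_rng(1).integers(0, 4, n_sites))
        rate, age = 2.2e-9, 0.12 / 2.2e-9
        fractions = []
        for seed in range(n_seeds):
            _, count = mutate_jc(seq, rate, age, np.random.default_rng(seed))
            fractions.append(count / n_sites)
        se = math.sqrt(p_true * (1 - p_true) / (n_sites * n_seeds))
        assert abs(np.mean(fractions) - p_true) < 3 * se

    def test_count_equals_hamming_distance(self):
        rng = np.random.default_rng(3)
        seq = "ACGT" * 500
        out, count = mutate_jc(seq, 1e-9, 1e8, rng)
        assert count == sum(a != b for a, b in zip(seq, out))


class TestSimulateBurst:
    def test_zero_copies(self, master865):
        burst = BurstModel(n_copies_per_variant={"full": 0, "deletion_derivative": 0}, seed=1)
        sim = simulate_burst(master865, burst, genome_length=10_000, gene_density=0.0)
        assert sim.truth == []
        assert sim.hits == []
        assert len(sim.genome) == 10_000

    def test_tsd_flanks_every_insertion(self, mixed_burst):
        for t in mixed_burst.truth:
            assert mixed_burst.genome[t.start - 2 : t.start] == "TA"
            assert mixed_burst.genome[t.end : t.end + 2] == "TA"

    def test_length_conservation(self, mixed_burst):
        copy_bp = sum(t.end - t.start for t in mixed_burst.truth)
        n = len(mixed_burst.truth)
        assert len(mixed_burst.genome) == 500_000 + copy_bp + 2 * TSD_LEN * n

    def test_genome_sequence_matches_truth(self, mixed_burst, master865):
        # the inserted sequence at each truth interval is the (possibly
        # reverse-complemented) mutated copy with the right length
        for t in mixed_burst.truth:
            span = t.end - t.start
            expect = 865 if t.variant == "full" else 865 - 261
            assert span == expect

    def test_truth_msa_consistency(self, mixed_burst, master865):
        rows = dict(mixed_burst.msa)
        for t in mixed_burst.truth:
            row = rows[t.copy_id]
            p = p_distance(row, master865.sequence)
            aligned = 865 if t.variant == "full" else 865 - 261
            assert p == pytest.approx(t.realized_substitutions / aligned, abs=1e-12)

    def test_expected_p_invariant(self, mixed_burst):
        for t in mixed_burst.truth:
            formula = 0.75 * (1 - math.exp(-(4 / 3) * 2.2e-9 * t.age))
            assert t.expected_p == pytest.approx(formula, rel=1e-12)

    def test_mean_p_to_master_parameter_recovery(self, master865):
        # 200 + 200 copies at rate*age_mean = 0.20: mean p within 3 s.e.
        # of (3/4)(1 - e^{-0.2667}) = 0.17537
        rate = 2.2e-9
        age = 0.20 / rate
        burst = BurstModel(
            rate_s=rate,
            age_mean=age,
            age_sd=0.0,
            n_copies_per_variant={"full": 200, "deletion_derivative": 200},
            seed=17,
        )
        sim = simulate_burst(master865, burst, genome_length=1_500_000, gene_density=0.0)
        p_true = 0.75 * (1 - math.exp(-(4 / 3) * 0.20))
        assert p_true == pytest.approx(0.17555, abs=5e-5)
        ps = [
            p_distance(row, master865.sequence)
            for _, row in sim.msa
        ]
        total_sites = 200 * 865 + 200 * (865 - 261)
        se = math.sqrt(p_true * (1 - p_true) / total_sites)
        assert abs(np.mean(ps) - p_true) < 3 * se * 1.5  # variant-length weighting slack

    def test_genome_too_small_raises(self, master865):
        burst = BurstModel(n_copies_per_variant={"full": 100, "deletion_derivative": 0}, seed=1)
        with pytest.raises(ValueError, match="genome_length"):
            simulate_burst(master865, burst, genome_length=150, gene_density=0.0)

    def test_seeded_determinism_byte_identical(self, master865, tmp_path):
        burst = BurstModel(
            n_copies_per_variant={"full": 10, "deletion_derivative": 10},
            fragmentation_prob=0.5,
            seed=99,
        )
        out = []
        for run in ("a", "b"):
            sim = simulate_burst(master865, burst, genome_length=100_000, gene_density=0.2)
            paths = write_simulation(sim, tmp_path / run)
            out.append({k: p.read_bytes() for k, p in paths.items()})
        assert out[0] == out[1]

    def test_fragmented_hits_stay_within_copy(self, fragmented_burst):
        by_interval = {}
        for t in fragmented_burst.truth:
            by_interval[(t.start, t.end)] = t
        for h in fragmented_burst.hits:
            assert any(
                s <= h.target_start and h.target_end <= e for (s, e) in by_interval
            )

    def test_fragmentation_produces_extra_hits(self, fragmented_burst, mixed_burst):
        # 50 full + 50 derivative with fragmentation on must emit more hit
        # records than copies-with-deletion alone would
        assert len(fragmented_burst.hits) > 150

    def test_genes_have_subfeatures_with_parents(self, mixed_burst):
        kinds = {g.feature_kind for g in mixed_burst.genes}
        assert {"gene", "mRNA", "CDS", "five_prime_UTR", "three_prime_UTR"} <= kinds
        mrna_ids = {g.id for g in mixed_burst.genes if g.feature_kind == "mRNA"}
        for g in mixed_burst.genes:
            if g.feature_kind in ("CDS", "five_prime_UTR", "three_prime_UTR"):
                assert g.parent_id in mrna_ids
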