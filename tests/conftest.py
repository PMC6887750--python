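import numpy as np
import pytest

from mitewave.synthetic_data import BurstModel, make_master, simulate_burst


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def master865():
    return make_master(length=865, tir_length=24, deletion_window=(300, 561), seed=7)


@pytest.fixture(scope="session")
def mixed_burst(master865):
    """60 full + 60 derivative copies, unfragmented, in a 0.5 Mb genome."""
    burst = BurstModel(
        rate_s=2.2e-9,
        age_mean=50e6,
        age_sd=2.5e6,
        n_copies_per_variant={"full": 60, "deletion_derivative": 60},
        fragmentation_prob=0.0,
        seed=11,
    )
    return simulate_burst(master865, burst, genome_length=500_000, gene_density=0.2)


@pytest.fixture(scope="session")
def fragmented_burst(master865):
    """Every copy's hit record fragmented (up to 4 pieces)."""
    burst = BurstModel(
        rate_s=2.2e-9,
        age_mean=50e6,
        age_sd=2.5e6,
        n_copies_per_variant={"full": 50, "deletion_derivative": 50},
        fragmentation_prob=1.0,
        max_fragments=4,
        seed=13,
    )
    return simulate_burst(master865, burst, genome_length=500_000, gene_density=0.1)
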