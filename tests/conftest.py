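import pytest

from charauth.synthetic_data import (
    CONTAMINANT_ID,
    DamageModel,
    GenomeSet,
    PoolConfig,
    default_samples,
    generate_genomes,
    simulate_pool,
)


@pytest.fixture(scope="session")
def small_genomes() -> GenomeSet:
    """One 60 kb target genome plus a 30 kb contaminant genome."""
    target = generate_genomes(1, [60000], 0.45, 101)
    contam = generate_genomes(1, [30000], 0.45, 202)
    return GenomeSet(
        [("genome_1", target["genome_1"]), (CONTAMINANT_ID, contam["genome_1"])]
    )


@pytest.fixture(scope="session")
def damaged_pool(small_genomes):
    """2 samples x 4000 damaged reads (d5=d3=0.3, lam=0.5), no hopping."""
    samples = default_samples(2, source_genome="genome_1")
    config = PoolConfig(
        samples=tuple(samples),
        hop_rate=0.0,
        n_reads_per_sample=4000,
        damage=DamageModel(d5=0.3, d3=0.3, lam=0.5),
        seed=9,
    )
    reads, truth = simulate_pool(config, small_genomes)
    return config, reads, truth


@pytest.fixture(scope="session")
def hopping_pool(small_genomes):
    """4 samples x 50 000 reads with 0.3% index hopping, read length 100.

    Inserts are log-normal with mean 45 (sd 12) so most reads leave enough
    cycles to sequence the adapter prefix and the index in-read.
    """
    samples = default_samples(4, source_genome="genome_1")
    config = PoolConfig(
        samples=tuple(samples),
        hop_rate=0.003,
        read_len=100,
        insert_mean=45.0,
        insert_sd=12.0,
        n_reads_per_sample=50000,
        seed=1,
    )
    reads, truth = simulate_pool(config, small_genomes)
    return config, reads, truth
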