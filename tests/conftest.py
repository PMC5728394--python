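import numpy as np
import pytest

from emribomap import CircularGenome, SimConfig, embed_ribos, generate_genome, simulate_reads


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(genome_length=4_000, n_sites=300, read_length=40, reads_per_site=1, seed=17)


@pytest.fixture(scope="session")
def small_genome(small_config) -> CircularGenome:
    return generate_genome(small_config)


@pytest.fixture(scope="session")
def small_truth(small_genome, small_config):
    return embed_ribos(small_genome, small_config)


@pytest.fixture(scope="session")
def small_reads(small_genome, small_truth, small_config):
    return simulate_reads(small_genome, small_truth, small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
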