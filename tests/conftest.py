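import numpy as np
import pytest

BASES = np.array(list("ACGT"))


def random_dna(rng, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_deletion_collection():
    """30 genomes, one 5 kb deletion-born fusion in a ~10-genome clade."""
    from fusescan.synthetic_data import PlantedEvent, generate_collection
    events = [PlantedEvent("deletion_fusion", 10, 5000)]
    return generate_collection(30, events, genome_len=60_000, seed=1)


@pytest.fixture(scope="session")
def small_insertion_collection():
    """30 genomes, one 3 kb MGE cargo insertion in a ~10-genome clade."""
    from fusescan.synthetic_data import PlantedEvent, generate_collection
    events = [PlantedEvent("cargo_insertion", 10, 3000, gene_len=600)]
    return generate_collection(30, events, genome_len=60_000, seed=2)
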