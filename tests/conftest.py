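import pytest

from bsfusion import TargetPair, make_toy_reference, plant_fusion, simulate_dataset
from bsfusion.simgen import SimConfig


@pytest.fixture(scope="session")
def toy_genome():
    return make_toy_reference(lengths=(20_000, 20_000), seed=11)


@pytest.fixture(scope="session")
def allele(toy_genome):
    return plant_fusion(toy_genome, 10_000, 9_000)


@pytest.fixture(scope="session")
def target(toy_genome):
    return TargetPair(toy_genome.gene_a.as_region(), toy_genome.gene_b.as_region())


@pytest.fixture(scope="session")
def sim_full(toy_genome, allele):
    """Pure fusion-positive library at modest depth."""
    cfg = SimConfig(fraction=1.0, depth=20, seed=7)
    return simulate_dataset(toy_genome, allele, cfg)


@pytest.fixture(scope="session")
def sim_negative(toy_genome):
    """Fusion-negative library (wildtype only)."""
    cfg = SimConfig(fraction=0.0, depth=10, seed=8)
    return simulate_dataset(toy_genome, None, cfg)
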