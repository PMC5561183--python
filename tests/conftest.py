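from pathlib import Path

import pytest

from mcekit.architecture import architectures_from_hits
from mcekit.simulate import SimulationConfig, ecoli_fixture, simulate_dataset

FIXTURES = Path(__file__).parent / "fixtures"


@pytest.fixture(scope="session")
def small_dataset():
    """A small noisy simulation shared across read-only tests."""
    config = SimulationConfig(
        seed=42,
        n_phyla=4,
        species_per_phylum=5,
        genomes_per_species=2,
        decoy_hit_rate=0.5,
        overlap_conflict_rate=0.1,
        far_gene_fraction=0.3,
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def small_architectures(small_dataset):
    return architectures_from_hits(
        small_dataset.hits,
        protein_ids=[p.protein_id for p in small_dataset.proteins],
    )


@pytest.fixture(scope="session")
def ecoli():
    return ecoli_fixture()


@pytest.fixture
def fixtures_dir():
    return FIXTURES
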