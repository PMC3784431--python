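import pytest
from hypothesis import settings

from nichecomp.orthology import build_families
from nichecomp.synthetic import SimulationConfig, generate

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


SMALL_CONFIG = dict(
    n_genomes_A=3,
    n_genomes_B=2,
    n_core=12,
    n_specific_A=6,
    n_specific_B=4,
    n_private_per_genome=2,
    divergence=0.10,
    mean_protein_length=90.0,
    sd_protein_length=15.0,
    seed=7,
)


@pytest.fixture(scope="session")
def small_dataset():
    """One small planted pangenome shared across the suite."""
    return generate(SimulationConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_families(small_dataset):
    return build_families(list(small_dataset.proteomes.values()))
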