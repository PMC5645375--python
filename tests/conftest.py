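import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bsmeth.config import SimConfig
from bsmeth.simulate import simulate_bisulfite_reads, simulate_genome, simulate_methylome

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        seed=7,
        genome_length=12_000,
        n_genes=6,
        n_repeats=8,
        target_depth=12,
        lambda_length=3_000,
        lambda_fraction=0.15,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """One simulated study shared across read-only tests."""
    genome, genes, repeats = simulate_genome(small_config)
    methylome = simulate_methylome(genome, genes, small_config)
    reads, truth = simulate_bisulfite_reads(genome, methylome, small_config)
    return {
        "config": small_config,
        "genome": genome,
        "genes": genes,
        "repeats": repeats,
        "methylome": methylome,
        "reads": reads,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
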