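import numpy as np
import pytest

from viromescope import synthetic
from viromescope.reads import KmerIndex


@pytest.fixture(scope="session")
def small_reference():
    """20 genomes, 1-2 kb, default host taxonomy."""
    return synthetic.generate_reference_db(20, length_range=(1000, 2000), rng_seed=7)


@pytest.fixture(scope="session")
def host_genome():
    return synthetic.generate_host_genome(length=20_000, rng_seed=8)


@pytest.fixture(scope="session")
def small_design(small_reference):
    return synthetic.design_communities(
        small_reference, group_sizes=(6, 4), base_richness=10, rng_seed=9
    )


@pytest.fixture(scope="session")
def small_simulation(small_reference, small_design, host_genome):
    """5k reads/sample for the first two samples only (kept small for speed)."""
    cfg = synthetic.SimulationConfig(reads_per_sample=5000, rng_seed=10)
    reads_by_sample, truth = synthetic.simulate_reads(
        small_reference, small_design, host_genome, cfg
    )
    return reads_by_sample, truth, cfg


@pytest.fixture(scope="session")
def viral_index(small_reference):
    return KmerIndex(small_reference.sequences())


@pytest.fixture(scope="session")
def host_index(host_genome):
    return KmerIndex({"host": host_genome})


@pytest.fixture
def rng():
    return np.random.default_rng(0)
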