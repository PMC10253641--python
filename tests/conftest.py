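import pytest
from hypothesis import HealthCheck, settings

from symsift.config import SimulationConfig
from symsift import synthetic

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


SMALL_CONFIG = SimulationConfig(
    seed=7,
    n_host_contigs=40,
    n_symbiont_contigs=20,
    n_chimeras=4,
    n_hgt_contigs=4,
    host_genome_len=1_200_000,
    symbiont_genome_len=700_000,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully featured synthetic metagenome shared across tests."""
    return synthetic.simulate(SMALL_CONFIG)
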