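import pytest

from flafam.synthetic import SimulationConfig, generate_genome_pair


@pytest.fixture(scope="session")
def genome_pair():
    """One default synthetic genome pair shared across tests (seed 11)."""
    cfg = SimulationConfig(seed=11)
    genome_a, genome_b, truth = generate_genome_pair(cfg)
    return cfg, genome_a, genome_b, truth
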