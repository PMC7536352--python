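import pytest

from cpkit.synthetic_data import GenomeSpec, simulate_genome


@pytest.fixture(scope="session")
def toy_genome():
    """A 35-kb quadripartite genome (LSC 20 kb, IR 6 kb, SSC 3 kb) + truth."""
    return simulate_genome(GenomeSpec(seed=1))


@pytest.fixture(scope="session")
def small_genome():
    """A 4.4-kb quadripartite genome for brute-force comparisons."""
    return simulate_genome(GenomeSpec(lsc_bp=2500, ir_bp=600, ssc_bp=700, seed=2))
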