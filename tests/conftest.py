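import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from divcomp.synthio import SimConfig, simulate_snp_pools, simulate_ssr_genotypes

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A scaled-down study: 4 populations, small panels, fixed seed."""
    return SimConfig(
        n_populations=4, n_snps=2000, n_genes=60, gene_length=200,
        ssr_loci_cross=5, ssr_loci_specific=4, seed=7,
    )


@pytest.fixture(scope="session")
def small_snp_sim(small_config):
    return simulate_snp_pools(small_config)


@pytest.fixture(scope="session")
def small_ssr_table(small_config):
    table, truth = simulate_ssr_genotypes(small_config)
    return table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
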