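import numpy as np
import pytest

from cispred import ArchitectureConfig, simulate_gene, simulate_genotypes


@pytest.fixture(scope="session")
def small_genotypes():
    """120 × 60 LD-structured dosage matrix shared across fast tests."""
    return simulate_genotypes(120, 60, seed=7)


@pytest.fixture(scope="session")
def medium_genotypes():
    """400 × 200 matrix for tests that need realistic estimator behaviour."""
    return simulate_genotypes(400, 200, seed=19)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def polygenic_gene(medium_genotypes):
    cfg = ArchitectureConfig("II", total_pve=0.5, seed=5)
    return simulate_gene(medium_genotypes, cfg, 0)
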