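import numpy as np
import pytest

from microbiability import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Fast cohort: 120 individuals, 300 SNPs, 80 ASVs in 12 genera."""
    return SimulationConfig(
        n_individuals=120,
        n_snps=300,
        n_asvs=80,
        n_genera=12,
        n_traits=3,
        h2_true=0.30,
        m2_true=0.25,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
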