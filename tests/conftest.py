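import numpy as np
import pytest

from gutsem import ChainConfig, gibbs_sem, simulate_population


@pytest.fixture(scope="session")
def small_population():
    """A small simulated study: 120 animals, dense GRM from 200 SNPs."""
    return simulate_population(
        n_animals=120, n_litters=60, n_cages=58, n_snps=200, seed=42
    )


@pytest.fixture(scope="session")
def short_chain(small_population):
    """A short but real posterior chain on the small population."""
    data, _, _ = small_population
    cfg = ChainConfig(n_iter=600, burn_in=200, thin=2, seed=7)
    return gibbs_sem(data, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
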