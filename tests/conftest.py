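import numpy as np
import pytest

from pbscan.simdata import SimulationConfig, simulate_dataset
from pbscan import gl as glmod


@pytest.fixture(scope="session")
def small_dataset():
    """A small 3-population low-coverage dataset shared across tests."""
    cfg = SimulationConfig(
        n_sites=800,
        chrom_length=800_000,
        n_individuals=(12, 10, 10),
        drift=(0.068, 0.020, 0.012),
        mean_depth=2.0,
        error_rate=0.01,
        seed=11,
    )
    truth, pileup = simulate_dataset(cfg)
    table = glmod.compute_gl_table(pileup)
    return cfg, truth, pileup, table


@pytest.fixture
def rng():
    return np.random.default_rng(123)
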