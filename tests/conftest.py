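import numpy as np
import pytest

from riskstrat import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared by read-only tests."""
    cfg = SimulationConfig(n_participants=2_000, n_variants=100, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    return small_sim[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
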