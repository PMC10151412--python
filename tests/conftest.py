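import numpy as np
import pytest
from hypothesis import settings

from rangex import SimParams, run

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231)


@pytest.fixture(scope="session")
def small_run():
    """One modest expansion with full birth logging, shared across tests."""
    params = SimParams(mu=1.5, p=0.5, K=10, m_stop=30 * 100, seed=42)
    return run(params, allele_mode="unique", record_births=True)


@pytest.fixture(scope="session")
def pioneer_run():
    """A longer unique-allele run used for pioneer/saturation analyses."""
    params = SimParams(mu=1.5, p=0.5, K=10, m_stop=100 * 100, seed=7)
    return run(params, allele_mode="unique", record_births=True)
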