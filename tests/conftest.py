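import numpy as np
import pytest

from sgscan.scenarios import neutral_scenario, nfds_scenario, sweep_scenario
from sgscan.simulate import simulate_population

N_SEEDS = 20


@pytest.fixture(scope="session")
def neutral_truth():
    """One neutral replicate shared by cheap unit tests."""
    return simulate_population(neutral_scenario(1))


@pytest.fixture(scope="session")
def neutral_batch():
    return [simulate_population(neutral_scenario(s)) for s in range(1, N_SEEDS + 1)]


@pytest.fixture(scope="session")
def sweep_batch():
    return [simulate_population(sweep_scenario(s)) for s in range(1, N_SEEDS + 1)]


@pytest.fixture(scope="session")
def nfds_batch():
    return [simulate_population(nfds_scenario(s)) for s in range(1, N_SEEDS + 1)]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
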