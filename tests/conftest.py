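import numpy as np
import pytest

from messt.design import SessionConfig, build_schedule
from messt.race import ParticipantModel, simulate_session


@pytest.fixture(scope="session")
def default_config():
    return SessionConfig()


@pytest.fixture(scope="session")
def small_config():
    # one short block per category-balanced chunk; fast to simulate
    return SessionConfig(n_trials=120, n_blocks=2)


@pytest.fixture(scope="session")
def stationary_participant():
    return ParticipantModel.stationary(mu=450, sigma=80, tau=100, ssrt=200)


@pytest.fixture(scope="session")
def simulated_session(default_config, stationary_participant):
    """One full 600-trial session under seed 1 (shared, read-only)."""
    schedule = build_schedule(default_config, seed=1)
    trials, state = simulate_session(schedule, stationary_participant,
                                     default_config, seed=1)
    return schedule, trials, state


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
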