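import numpy as np
import pytest

from carryover import SimulationConfig, simulate_immersion, simulate_phenology


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: 13 logger bird-seasons, 5 history-only birds."""
    return SimulationConfig(
        rp_category_counts={"SUCCESS": 6, "FAIL": 4, "SKIP": 3},
        n_birds_history_only=5,
        n_females_history_only=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_phenology(small_config):
    return simulate_phenology(small_config)


@pytest.fixture(scope="session")
def small_immersion(small_config, small_phenology):
    return simulate_immersion(small_config, small_phenology)


@pytest.fixture(scope="session")
def default_phenology():
    """Full-size phenology table (111 bird-seasons, 64/29/18)."""
    return simulate_phenology(SimulationConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
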