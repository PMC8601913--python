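import numpy as np
import pytest

from snailselect.synthetic import (
    SimulationScenario,
    recovery_scenario,
    simulate_population,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A small mainland-like simulated dataset shared across tests."""
    scen = recovery_scenario(seed=42, N=200, T=8)
    return simulate_population(scen)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
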