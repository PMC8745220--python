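import numpy as np
import pytest

from varfunnel.synthetic_data import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic study at the default (study-scale) configuration."""
    return simulate_all(SimulationConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
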