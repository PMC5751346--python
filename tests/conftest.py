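import numpy as np
import pytest

from permeatrace import BilayerSimConfig, CellConfig, simulate_bilayer_trajectory


@pytest.fixture
def cell():
    """Standard cell: V_r=15 mL, V_i=1.5 mL, A=1.23 cm^2, C_0=2000 ug/mL."""
    return CellConfig()


@pytest.fixture(scope="session")
def small_bilayer():
    """A short default-roster bilayer trajectory shared across tests."""
    return simulate_bilayer_trajectory(BilayerSimConfig(n_frames=200, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
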