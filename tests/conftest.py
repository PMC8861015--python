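import numpy as np
import pytest

from swnforce.topology import ModularNetworkConfig, build_modular_swn
from swnforce.neuron import sample_params


@pytest.fixture(scope="session")
def small_network():
    """A 125-neuron modular network: 2 modules of 50 exc + 25 inhibitory."""
    cfg = ModularNetworkConfig(
        n_modules=2, module_size=50, n_inhibitory=25, seed=42
    )
    return build_modular_swn(cfg)


@pytest.fixture(scope="session")
def small_params(small_network):
    return sample_params(small_network.neuron_type, seed=7)


@pytest.fixture(scope="session")
def default_network():
    """The full 1000-neuron modular small-world network (8x100 + 200)."""
    return build_modular_swn(ModularNetworkConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(123)
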