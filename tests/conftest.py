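import numpy as np
import pytest

from seqreservoir import Reservoir, TopologyConfig, build_topology


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_topology():
    """A 50-neuron reservoir over a 7x7 input grid, deterministic wiring."""
    return build_topology(TopologyConfig(n_inputs=49, n_reservoir=50, rng_seed=7))


@pytest.fixture
def small_net(small_topology):
    return Reservoir(small_topology)
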