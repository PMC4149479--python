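import numpy as np
import pytest

from attractorctl import build_network, two_state


@pytest.fixture
def chain_net():
    """1 -> 2 -> 3."""
    return build_network([(1, 2), (2, 3)])


@pytest.fixture
def diamond_net():
    """1 -> {2,3} -> 4."""
    return build_network([(1, 2), (1, 3), (2, 4), (3, 4)])


@pytest.fixture
def chain_attractors(chain_net):
    """All-differential attractor pair on the chain."""
    normal = {1: 1, 2: 1, 3: 1}
    cancer = {n: -s for n, s in normal.items()}
    return two_state(chain_net, normal, cancer)


def all_differential(net, rng=None):
    """Attractor pair with cancer = -normal on every node."""
    rng = rng or np.random.default_rng(0)
    normal = {int(n): int(rng.choice([-1, 1])) for n in net.graph.nodes}
    return two_state(net, normal, {n: -s for n, s in normal.items()})
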