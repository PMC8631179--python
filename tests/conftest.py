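import numpy as np
import pytest

from gitr.network import SelfAssemblyNetwork, StableState, TransitionState
from gitr.pdl1 import pdl1_network, random_network


@pytest.fixture
def pdl1():
    return pdl1_network()


@pytest.fixture
def two_state_net():
    """Two dimer states over one shared barrier, distinct energies."""
    return SelfAssemblyNetwork(
        states=(
            StableState("S1", 2, -4.0),
            StableState("S2", 2, -6.0),
        ),
        transitions=(
            TransitionState("T1", 1.0, (("S1", 1.0), ("S2", 1.0))),
        ),
        temperature=310.0,
        c0_monomer=1.0,
    )


@pytest.fixture
def random_net_factory():
    """Seeded random connected bipartite networks of bounded size."""

    def make(seed, n_states=None, n_transitions=None):
        rng = np.random.default_rng(seed)
        ns = n_states or int(rng.integers(1, 7))
        nt = n_transitions or int(rng.integers(1, 5))
        return random_network(ns, nt, seed=seed)

    return make
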