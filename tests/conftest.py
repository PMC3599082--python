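import numpy as np
import pytest

from nrbn.fixtures import swap_net
from nrbn.network import BooleanNetwork, generate_er_network


@pytest.fixture(scope="session")
def swap():
    """2-node mutual-copy net: fixed points (0,0), (1,1) and one 2-cycle."""
    return swap_net()


@pytest.fixture(scope="session")
def constant_net():
    """Every rule constant 1: a single all-ones fixed point."""
    return BooleanNetwork(
        n=4,
        k_in=2,
        inputs=np.array([[1, 2], [2, 3], [3, 0], [0, 1]], dtype=np.int32),
        tables=np.ones((4, 4), dtype=np.uint8),
    )


@pytest.fixture(scope="session")
def critical_nets10():
    """A small seeded ensemble of critical 10-node nets."""
    return [generate_er_network(10, 2, 0.5, seed=s) for s in range(12)]


def random_column_stochastic(rng, m, zero_frac=0.4, diag_boost=1.0):
    """Random left-stochastic matrix with controllable sparsity."""
    A = rng.random((m, m))
    A[rng.random((m, m)) < zero_frac] = 0.0
    A[np.diag_indices(m)] += diag_boost
    s = A.sum(axis=0)
    s[s == 0] = 1.0
    A = A / s
    # columns that became all-zero get a self-loop
    for j in range(m):
        if A[:, j].sum() == 0:
            A[j, j] = 1.0
    return A
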