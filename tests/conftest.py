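import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose oracles.py

from hypermem import Hyperedge, TemporalHypergraph, enumerate_hyperedges


def random_hypergraph(rng, num_nodes, max_order, num_steps, density=0.15):
    """A temporal hypergraph whose candidate hyperedges are active i.i.d."""
    candidates = enumerate_hyperedges(num_nodes, max_order)
    snapshots = [
        frozenset(e for e in candidates if rng.random() < density)
        for _ in range(num_steps)
    ]
    return TemporalHypergraph(
        num_nodes=num_nodes, max_order=max_order, snapshots=snapshots
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_random_th():
    return random_hypergraph


@pytest.fixture
def small_th():
    """T=4, N=4, D=3 hypergraph with hand-picked snapshots."""
    snaps = [
        [(0, 1), (0, 1, 2)],
        [(0, 1), (1, 2)],
        [(0, 1, 2), (0, 1, 3)],
        [],
    ]
    return TemporalHypergraph(num_nodes=4, max_order=3, snapshots=snaps)
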