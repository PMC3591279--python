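import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))   # make oracles importable

from connectopt import AnnealSchedule, Digraph, PositionTable, SpatialNetwork
from connectopt.synth import ring_layout


@pytest.fixture
def fast_schedule():
    """Short cooling schedule for unit-level annealing tests."""
    return AnnealSchedule(steps_per_T=300, cool=0.85, t_stop_ratio=1e-4)


@pytest.fixture
def ring12():
    return ring_layout(12)


@pytest.fixture
def cycle4():
    """Directed 4-cycle."""
    return Digraph.from_edges([(0, 1), (1, 2), (2, 3), (3, 0)], 4)


@pytest.fixture
def toy_spatial():
    """5 nodes with hand-set 2-D coordinates and 6 directed links."""
    pos = PositionTable(("a", "b", "c", "d", "e"),
                       np.array([[0.0, 0.0], [3.0, 0.0], [3.0, 4.0],
                                 [0.0, 4.0], [1.0, 1.0]]))
    g = Digraph.from_edges([(0, 1), (1, 2), (2, 3), (3, 0), (0, 4), (4, 2)], 5)
    return SpatialNetwork(g, pos)


def random_strong_digraph(n, K, seed):
    from connectopt import random_connected_digraph

    return random_connected_digraph(n, K, np.random.default_rng(seed))
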