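import numpy as np
import pytest

import eegfu


@pytest.fixture(scope="session")
def table1():
    """The 12-node worked-example network and its grid adjacency."""
    return eegfu.table1_network()


@pytest.fixture(scope="session")
def grid_layout_3x4():
    return eegfu.grid_layout(3, 4)


@pytest.fixture(scope="session")
def grid_adjacency(grid_layout_3x4):
    return eegfu.voronoi_adjacency(grid_layout_3x4)


def random_grid_network(seed: int, edge_prob: float = 0.4, theta: float = 0.2):
    """Random weighted network on the 3x4 grid: each pair gets a weight
    in [theta, 1] with probability ``edge_prob``, else 0."""
    layout = eegfu.grid_layout(3, 4)
    rng = np.random.default_rng(seed)
    n = len(layout)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_prob:
                w = rng.uniform(theta, 1.0)
                mat[i, j] = mat[j, i] = w
    return eegfu.CoherenceNetwork(layout, mat, theta)
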