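import numpy as np
import pytest

from adcascade.graph import build_graph, partition_adjacency


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path_graph():
    """a - b - c path, centered on a."""
    return build_graph([(0, 1), (1, 2)], 3, center_index=0)


@pytest.fixture
def toy_adjacency():
    """Partitioned adjacency of a small 5-node tree."""
    g = build_graph([(0, 1), (1, 2), (1, 3), (3, 4)], 5, center_index=0)
    return partition_adjacency(g)


def random_tree(rng: np.random.Generator, n_nodes: int):
    """Uniform random labeled tree edges via random parent attachment."""
    edges = []
    for v in range(1, n_nodes):
        edges.append((int(rng.integers(0, v)), v))
    return edges
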