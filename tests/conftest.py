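import itertools

import numpy as np
import pytest

from lpamni import Network, load_fixture


@pytest.fixture(scope="session")
def karate():
    return load_fixture("karate")


@pytest.fixture(scope="session")
def two_cliques_net():
    return load_fixture("two_cliques")


@pytest.fixture(scope="session")
def two_triangles():
    return load_fixture("two_triangles")


def random_network(rng: np.random.Generator, n: int, p: float = 0.5) -> Network:
    """Erdos-Renyi graph with at least one edge, nodes 0..n-1."""
    while True:
        edges = [
            (i, j) for i, j in itertools.combinations(range(n), 2)
            if rng.random() < p
        ]
        if edges:
            return Network(edges, nodes=range(n))


def random_partition(rng: np.random.Generator, nodes, k: int) -> dict:
    return {u: int(rng.integers(k)) for u in nodes}
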