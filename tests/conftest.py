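import networkx as nx
import numpy as np
import pytest

from btsnet import InteractionNetwork


@pytest.fixture
def path4() -> InteractionNetwork:
    """Path graph a-b-c-d."""
    return InteractionNetwork.from_edges([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def two_cliques() -> InteractionNetwork:
    """Two disjoint 6-cliques, nodes a00..a05 and b00..b05."""
    g = nx.Graph()
    for prefix in ("a", "b"):
        nodes = [f"{prefix}{i:02d}" for i in range(6)]
        g.add_edges_from(
            (u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]
        )
    return InteractionNetwork.from_networkx(g)


@pytest.fixture
def bipartite_k88() -> InteractionNetwork:
    """Complete bipartite K(8,8): left l0..l7, right r0..r7."""
    return InteractionNetwork.from_edges(
        (f"l{i}", f"r{j}") for i in range(8) for j in range(8)
    )


def random_network(n: int, p: float, seed: int) -> InteractionNetwork:
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.random((n, n)) < p, k=1)
    A = (upper | upper.T).astype(np.uint8)
    return InteractionNetwork([f"v{i:03d}" for i in range(n)], A)
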