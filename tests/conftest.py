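import networkx as nx
import pytest

from hubnet import SyntheticSpec, generate_ppi


def random_connected_graph(n_nodes: int, seed: int, p: float = 0.35) -> nx.Graph:
    """Seeded Erdos-Renyi graph conditioned on connectivity (resample seed)."""
    attempt = seed
    while True:
        g = nx.gnp_random_graph(n_nodes, p, seed=attempt)
        if n_nodes <= 1 or nx.is_connected(g):
            return g
        attempt += 10_000


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Scaled-down generator spec for fast IO round trips."""
    return SyntheticSpec(seed=1, n_nodes=60, n_isolated=10, attachment_edges=3,
                         n_planted_hubs=3, planted_hub_boost=8)


@pytest.fixture(scope="session")
def small_net(small_spec):
    return generate_ppi(small_spec)


@pytest.fixture(scope="session")
def default_net():
    """Study-scale synthetic network (250 nodes, 75 isolated)."""
    return generate_ppi(SyntheticSpec(seed=1))
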