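import networkx as nx
import pytest

from funclust.cluster import Cluster, Clustering
from funclust.synthetic import SyntheticSpec


@pytest.fixture
def triangle_net():
    g = nx.Graph()
    g.add_weighted_edges_from([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])
    return g


@pytest.fixture
def path3_net():
    g = nx.Graph()
    g.add_weighted_edges_from([("a", "b", 1.0), ("b", "c", 1.0)])
    return g


@pytest.fixture
def small_spec():
    """Small planted-partition conditions for fast statistical tests."""
    return SyntheticSpec(
        blocks=8,
        block_size_range=(10, 20),
        hub_count=5,
        hub_degree=6,
        n_samples=16,
        seed=0,
    )


def chain_recipe_net():
    """21 singleton members v01..v21; connectors h01..h25, h_i linking
    v_i and v_{i+1} (indices wrapping past 21)."""
    g = nx.Graph()
    members = [f"v{i:02d}" for i in range(1, 22)]
    g.add_nodes_from(members)
    for i in range(1, 26):
        a = f"v{(i - 1) % 21 + 1:02d}"
        b = f"v{i % 21 + 1:02d}"
        g.add_edge(f"h{i:02d}", a)
        g.add_edge(f"h{i:02d}", b)
    return g, set(members)


def parallel_recipe_net(n_connectors=25):
    """21 singleton members; every connector links the same two members, so
    component count stalls at 20 and the addition cap is genuinely reached."""
    g = nx.Graph()
    members = [f"v{i:02d}" for i in range(1, 22)]
    g.add_nodes_from(members)
    for i in range(1, n_connectors + 1):
        g.add_edge(f"h{i:02d}", "v01")
        g.add_edge(f"h{i:02d}", "v02")
    return g, set(members)


def three_step_recipe_net():
    """5 singleton members; three connectors each merging one fresh pair, so
    the third addition lifts sc above 0.75 (0.4 -> 2/3 -> 6/7)."""
    g = nx.Graph()
    members = [f"v{i}" for i in range(1, 6)]
    g.add_nodes_from(members)
    g.add_edge("h1", "v1"), g.add_edge("h1", "v2")
    g.add_edge("h2", "v3"), g.add_edge("h2", "v4")
    g.add_edge("h3", "v1"), g.add_edge("h3", "v3")
    return g, set(members)


def clustering_of(*member_sets):
    return Clustering(clusters=[Cluster(members=set(m)) for m in member_sets])
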