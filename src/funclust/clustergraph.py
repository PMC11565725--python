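"""The cluster graph: a higher-order view where each node is a cluster.

The weight of edge (C, D) counts the network edges (binarized) with one
endpoint among C's original members and the other among D's; ReCIPE-added
nodes are excluded so overlapping clusters cannot double-count an edge.
Edges lighter than a threshold ``t`` (default 10) are dropped. Clusters
that broker between functional neighborhoods ("bridge" clusters) are ranked
by betweenness centrality on the thresholded graph.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .cluster import Clustering

logger = logging.getLogger(__name__)

__all__ = [
    "build_cluster_graph",
    "rank_bridge_clusters",
    "export_cluster_graph",
    "read_cluster_graph",
]


def build_cluster_graph(
    net: nx.Graph,
    clustering: Clustering,
    t: int = 10,
    slim_labels: dict[str, str] | None = None,
) -> nx.Graph:
    """Graph over clusters with crossing-edge-count weights, thresholded at ``t``.

    Node attributes: ``size`` (original member count) and ``slim_label``.
    Raises if the clusters' original member sets overlap.
    """
    owner: dict[str, str] = {}
    cg = nx.Graph()
    for c in clustering.clusters:
        cid = c.id if c.id is not None else min(c.members)
        for v in c.members:
            if v in owner:
                raise ValueError(
                    f"node {v!r} belongs to clusters {owner[v]!r} and {cid!r}"
                )
            owner[v] = cid
        label = (slim_labels or {}).get(cid, c.slim_label)
        cg.add_node(cid, size=c.size, slim_label=label or "unassigned")

    weights: dict[tuple[str, str], int] = {}
    for a, b in net.edges():
        ca, cb = owner.get(a), owner.get(b)
        if ca is None or cb is None or ca == cb:
            continue
        key = (ca, cb) if ca < cb else (cb, ca)
        weights[key] = weights.get(key, 0) + 1
    for (ca, cb), w in weights.items():
        if w >= t:
            cg.add_edge(ca, cb, weight=w)
    return cg


def rank_bridge_clusters(cg: nx.Graph, weighted: bool = False) -> list[tuple[str, float]]:
    """Clusters by descending betweenness centrality (ties by cluster id).

    Computed on the unweighted thresholded graph by default; ``weighted=True``
    uses inverse crossing counts as path lengths.
    """
    if cg.number_of_nodes() == 0:
        return []
    if weighted:
        for a, b, data in cg.edges(data=True):
            data["_dist"] = 1.0 / data["weight"]
        bc = nx.betweenness_centrality(cg, weight="_dist", normalized=True)
    else:
        bc = nx.betweenness_centrality(cg, normalized=True)
    return sorted(bc.items(), key=lambda kv: (-kv[1], kv[0]))


def export_cluster_graph(
    cg: nx.Graph,
    edges_path: str | Path,
    nodes_path: str | Path,
    min_weight: int | None = None,
) -> None:
    """Write edge-list and node-attribute TSVs (stable order, round-trips).

    ``min_weight`` refilters edges for presentation without rebuilding.
    """
    edge_rows = [
        (min(a, b), max(a, b), int(d["weight"]))
        for a, b, d in cg.edges(data=True)
        if min_weight is None or d["weight"] >= min_weight
    ]
    pd.DataFrame(sorted(edge_rows), columns=["clusterA", "clusterB", "weight"]).to_csv(
        edges_path, sep="\t", index=False
    )
    node_rows = [
        (v, int(d.get("size", 0)), d.get("slim_label", "unassigned"))
        for v, d in sorted(cg.nodes(data=True))
    ]
    pd.DataFrame(node_rows, columns=["cluster", "size", "slim_label"]).to_csv(
        nodes_path, sep="\t", index=False
    )


def read_cluster_graph(edges_path: str | Path, nodes_path: str | Path) -> nx.Graph:
    cg = nx.Graph()
    nodes = pd.read_csv(nodes_path, sep="\t", dtype={"cluster": str})
    for _, row in nodes.iterrows():
        cg.add_node(row["cluster"], size=int(row["size"]), slim_label=row["slim_label"])
    edges = pd.read_csv(edges_path, sep="\t", dtype={"clusterA": str, "clusterB": str})
    for _, row in edges.iterrows():
        cg.add_edge(row["clusterA"], row["clusterB"], weight=int(row["weight"]))
    return cg
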