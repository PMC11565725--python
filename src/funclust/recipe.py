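"""ReCIPE: greedy reconnection of fragmented clusters.

Spectral clusters of a DSD similarity often group nodes that share a minor
hub without being adjacent themselves, so the cluster-induced subgraph can
fall apart into many components. ReCIPE re-adds outside "connector"
proteins to such clusters, allowing controlled overlap between clusters.

For a cluster with ``n`` proteins whose induced subgraph has ``c``
connected components, the connectivity score is

    sc = 1 - (c - 1) / (n - 1)

(1 exactly when the cluster is connected). Candidates are nodes outside the
cluster with edges into at least a ``connect_ratio`` fraction of the
initial components; they are added in increasing order of full-network
degree (ties by node id), recomputing (n, c, sc) over members plus added
nodes after each addition, until ``sc > sc_threshold``, a cap of
``max_added`` additions is hit, or candidates run out. Edge weights are
ignored throughout: connectivity is topological.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field

import networkx as nx

from .cluster import Cluster, Clustering

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterConnectivity",
    "RecipeParams",
    "RecipeOutcome",
    "connectivity_score",
    "find_candidates",
    "reconnect",
]


@dataclass(frozen=True)
class ClusterConnectivity:
    """Size ``n``, component count ``c`` and score ``sc`` of a cluster."""

    n: int
    c: int
    sc: float


@dataclass(frozen=True)
class RecipeParams:
    connect_ratio: float = 0.10
    sc_threshold: float = 0.75
    max_added: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.connect_ratio <= 1:
            raise ValueError("connect_ratio must be in (0, 1]")
        if not 0 < self.sc_threshold <= 1:
            raise ValueError("sc_threshold must be in (0, 1]")
        if self.max_added < 0:
            raise ValueError("max_added must be >= 0")


@dataclass
class RecipeOutcome:
    """Why the greedy loop stopped for one cluster, and its trajectory."""

    reason: str  # "connected" | "above_threshold" | "threshold" | "cap" | "exhausted"
    initial_sc: float
    final_sc: float
    added: list[str] = field(default_factory=list)
    sc_trajectory: list[float] = field(default_factory=list)


def connectivity_score(net: nx.Graph, members: set[str]) -> ClusterConnectivity:
    """Connectivity of the subgraph induced by ``members`` (binarized edges)."""
    n = len(members)
    if n < 2:
        raise ValueError("connectivity score needs at least 2 members")
    missing = members - set(net.nodes())
    c = nx.number_connected_components(net.subgraph(members - missing)) + len(missing)
    sc = 1.0 - (c - 1) / (n - 1)
    return ClusterConnectivity(n=n, c=c, sc=sc)


def _components(net: nx.Graph, members: set[str]) -> list[set[str]]:
    present = members & set(net.nodes())
    comps = [set(cc) for cc in nx.connected_components(net.subgraph(present))]
    comps += [{v} for v in members - present]
    return comps


def find_candidates(
    net: nx.Graph,
    members: set[str],
    connect_ratio: float = 0.10,
) -> list[str]:
    """Connector candidates for a fragmented cluster, in greedy addition order.

    A node outside the cluster qualifies when it has edges into at least
    ``max(1, floor(connect_ratio * c))`` distinct components of the
    cluster-induced subgraph; candidates are ordered by increasing
    full-network degree, ties broken by node id.
    """
    comps = _components(net, members)
    c = len(comps)
    if c < 2:
        return []
    need = max(1, math.floor(connect_ratio * c))
    comp_of = {v: i for i, comp in enumerate(comps) for v in comp}
    candidates = []
    for v in net.nodes():
        if v in members:
            continue
        touched = {comp_of[u] for u in net.neighbors(v) if u in comp_of}
        if len(touched) >= need:
            candidates.append(v)
    candidates.sort(key=lambda v: (net.degree(v), v))
    return candidates


def _reconnect_cluster(
    net: nx.Graph, cluster: Cluster, params: RecipeParams
) -> RecipeOutcome:
    members = set(cluster.members)
    conn = connectivity_score(net, members)
    if conn.c == 1:
        return RecipeOutcome("connected", conn.sc, conn.sc)
    if conn.sc > params.sc_threshold:
        return RecipeOutcome("above_threshold", conn.sc, conn.sc)

    candidates = find_candidates(net, members, params.connect_ratio)
    added: list[str] = []
    trajectory: list[float] = []
    sc = conn.sc
    reason = "exhausted"
    for cand in candidates:
        if len(added) >= params.max_added:
            reason = "cap"
            break
        added.append(cand)
        sc = connectivity_score(net, members | set(added)).sc
        trajectory.append(sc)
        if sc > params.sc_threshold:
            reason = "threshold"
            break
    else:
        if len(added) >= params.max_added and candidates:
            reason = "cap"
    return RecipeOutcome(reason, conn.sc, sc, added, trajectory)


def reconnect(
    net: nx.Graph,
    clustering: Clustering,
    params: RecipeParams | None = None,
) -> tuple[Clustering, dict[str, RecipeOutcome]]:
    """Apply ReCIPE to every cluster; returns the new clustering and a report.

    Original members are never removed; re-added nodes are recorded in each
    cluster's ``recipe_added`` set, disjoint from ``members``. The report
    maps cluster id to the stop reason, the sc trajectory and the additions.
    """
    params = params or RecipeParams()
    out = copy.deepcopy(clustering)
    report: dict[str, RecipeOutcome] = {}
    for cluster in out.clusters:
        outcome = _reconnect_cluster(net, cluster, params)
        cluster.recipe_added = set(outcome.added)
        key = cluster.id if cluster.id is not None else min(cluster.members)
        report[key] = outcome
    n_touched = sum(1 for o in report.values() if o.added)
    logger.info(
        "ReCIPE re-added nodes to %d of %d clusters", n_touched, len(out.clusters)
    )
    return out, report
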