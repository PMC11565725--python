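"""Recursive hierarchical spectral clustering of a similarity matrix.

The network is first cut into ``K`` groups by spectral clustering of the
DSD-derived affinity matrix. Any resulting cluster of size ``n`` with
``round(n / D) >= 2`` is recursively re-partitioned into ``round(n / D)``
groups (round half up), which bounds retained cluster sizes by
``ceil(1.5 * D) - 1`` (29 for the default ``D = 20``). Clusters smaller
than ``M`` are discarded as uninformative.

The spectral step is the classical normalized-affinity embedding: the top
``k`` eigenvectors of ``D^{-1/2} S D^{-1/2}`` are row-normalized and
clustered with seeded k-means, which makes the whole procedure
deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "Cluster",
    "Clustering",
    "ClusteringParams",
    "round_half_up",
    "max_cluster_size",
    "spectral_partition",
    "hierarchical_cluster",
]


@dataclass
class Cluster:
    """A set of proteins plus bookkeeping filled in by later stages.

    ``members`` are the original (disjoint) spectral-clustering members;
    ``recipe_added`` holds connector nodes re-added afterwards and is always
    disjoint from ``members``.
    """

    members: set[str]
    recipe_added: set[str] = field(default_factory=set)
    id: str | None = None
    coherence: float | None = None
    functions: list[tuple[str, int]] = field(default_factory=list)
    slim_label: str | None = None
    summary: str | None = None

    def __post_init__(self) -> None:
        self.members = set(self.members)
        self.recipe_added = set(self.recipe_added)
        if self.members & self.recipe_added:
            raise ValueError("recipe_added must be disjoint from members")

    @property
    def size(self) -> int:
        return len(self.members)

    def all_members(self) -> set[str]:
        return self.members | self.recipe_added


@dataclass
class Clustering:
    """An ordered list of clusters plus the provenance of recursive splits."""

    clusters: list[Cluster]
    params: dict[str, Any] = field(default_factory=dict)
    tree: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if c.members & seen:
                raise ValueError("cluster member sets must be pairwise disjoint")
            seen |= c.members

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def assign_ids(self) -> None:
        """Deterministic ids: clusters ordered by size (desc), then smallest member."""
        order = sorted(
            self.clusters, key=lambda c: (-c.size, min(c.members) if c.members else "")
        )
        width = max(4, len(str(len(order))))
        for i, c in enumerate(order):
            c.id = f"C{i:0{width}d}"
        self.clusters = order


@dataclass(frozen=True)
class ClusteringParams:
    """Size-control knobs of the recursive splitting procedure."""

    K: int = 500
    D: int = 20
    M: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.D < 2:
            raise ValueError("D must be >= 2")
        if self.M < 1:
            raise ValueError("M must be >= 1")


def round_half_up(x: float) -> int:
    """round() with ties going up (1.5 -> 2), as the split rule requires."""
    return int(math.floor(x + 0.5))


def max_cluster_size(D: int) -> int:
    """Largest size a retained cluster can have: ceil(1.5*D) - 1."""
    return math.ceil(1.5 * D) - 1


def _check_similarity(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("similarity matrix must be symmetric")
    if np.any(S < 0):
        raise ValueError("similarity matrix must be non-negative")
    return S


def _spectral_embedding(S: np.ndarray, k: int) -> np.ndarray:
    """Top-k eigenvectors of the degree-normalized affinity, rows normalized."""
    n = S.shape[0]
    d = S.sum(axis=1)
    d[d <= 0] = 1.0  # all-zero rows cannot occur when diag(S) = 1
    inv_sqrt = 1.0 / np.sqrt(d)
    A = S * inv_sqrt[:, None] * inv_sqrt[None, :]
    A = (A + A.T) / 2.0
    _, vecs = scipy.linalg.eigh(A, subset_by_index=[n - k, n - 1])
    norms = np.linalg.norm(vecs, axis=1)
    norms[norms == 0] = 1.0
    return vecs / norms[:, None]


def spectral_partition(S: np.ndarray, k: int, seed: int = 0) -> list[np.ndarray]:
    """Partition the nodes of similarity matrix ``S`` into at most ``k`` groups.

    Returns a list of index arrays (non-empty, sorted, pairwise disjoint,
    covering ``range(n)``). Empty k-means groups are dropped without retry.
    """
    S = _check_similarity(S)
    n = S.shape[0]
    if k > n:
        raise ValueError(f"requested k={k} groups for only n={n} nodes")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return [np.arange(n)]
    emb = _spectral_embedding(S, k)
    n_init = 10 if k <= 50 else 1
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(emb)
    groups = [np.flatnonzero(labels == lab) for lab in range(k)]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < k:
        logger.debug("k-means produced %d of %d requested groups", len(groups), k)
    return groups


def _chunk_indices(idx: np.ndarray, k: int) -> list[np.ndarray]:
    """Deterministic equal-size fallback split (used only on k-means collapse)."""
    return [g for g in np.array_split(np.sort(idx), k) if g.size > 0]


def hierarchical_cluster(
    S: np.ndarray,
    nodes: Sequence[str],
    params: ClusteringParams | None = None,
) -> Clustering:
    """Recursively split ``S`` into size-bounded clusters.

    The initial partition uses ``params.K`` groups (lowered to ``n`` with a
    warning when the network is smaller). Every cluster of size ``n`` with
    ``round_half_up(n / D) >= 2`` is re-split into that many groups on the
    corresponding sub-block of ``S``; clusters below ``M`` are discarded.
    """
    params = params or ClusteringParams()
    S = _check_similarity(S)
    n = S.shape[0]
    if len(nodes) != n:
        raise ValueError("node list length must match similarity matrix")
    k0 = params.K
    if k0 > n:
        logger.warning("K=%d exceeds network size %d; lowering K to %d", k0, n, n)
        k0 = n

    leaves: list[np.ndarray] = []

    def split(idx: np.ndarray, k: int, depth: int) -> dict[str, Any]:
        groups = spectral_partition(S[np.ix_(idx, idx)], k, seed=params.seed)
        if len(groups) == 1 and k > 1:
            # degenerate embedding (duplicate rows); fall back to a
            # deterministic equal chunking so the size bound still holds
            logger.warning(
                "spectral partition collapsed to one group of %d at depth %d; "
                "splitting deterministically",
                idx.size,
                depth,
            )
            groups = _chunk_indices(np.arange(idx.size), k)
        children = []
        for g in groups:
            sub = idx[g]
            k_next = round_half_up(sub.size / params.D)
            if k_next >= 2 and sub.size < idx.size:
                children.append(split(sub, k_next, depth + 1))
            else:
                leaves.append(sub)
                children.append({"size": int(sub.size), "children": []})
        return {"size": int(idx.size), "children": children}

    tree = split(np.arange(n), k0, 0)

    node_arr = np.asarray(nodes, dtype=object)
    kept: list[Cluster] = []
    discarded = 0
    for leaf in leaves:
        if leaf.size < params.M:
            discarded += 1
            continue
        kept.append(Cluster(members=set(node_arr[leaf].tolist())))
    if discarded:
        logger.info("discarded %d clusters smaller than M=%d", discarded, params.M)

    clustering = Clustering(
        clusters=kept,
        params={"K": params.K, "D": params.D, "M": params.M, "seed": params.seed},
        tree=tree,
    )
    clustering.assign_ids()
    return clustering
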