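"""Cluster-level functional annotation and coherence statistics.

Functional similarity between two proteins is the Jaccard similarity of
their GO term sets; the coherence of a cluster is the mean similarity over
all its protein pairs. Significance is assessed against a null in which the
node -> GO-set assignment is permuted uniformly across the network (cluster
membership and hence node degrees are untouched), with a one-tailed
independent-samples t-test (real > shuffled). A global coherence cutoff can
be read off as the point where the density of real per-cluster coherences
first dominates the shuffled density.

Cluster functions are assigned by raw support: a term's support is the
number of member proteins (ReCIPE additions included) annotated with it,
and the cluster's slim label is the most frequent slim-projected term with
support of at least ``min_support`` (default 3), else "unassigned".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.stats

from .cluster import Cluster, Clustering
from .graphio import AnnotationTable

logger = logging.getLogger(__name__)

__all__ = [
    "CoherenceResult",
    "CrossingThreshold",
    "pair_similarity",
    "cluster_coherence",
    "coherence_profile",
    "shuffled_null",
    "coherence_test",
    "coherence_threshold",
    "assign_cluster_functions",
    "slim_label",
    "summary_card",
    "build_prompt",
    "annotate_clustering",
]


def pair_similarity(terms_u: set[str], terms_v: set[str]) -> float | None:
    """Jaccard similarity |u ∩ v| / |u ∪ v|; None when both sets are empty."""
    union = terms_u | terms_v
    if not union:
        return None
    return len(terms_u & terms_v) / len(union)


def cluster_coherence(cluster: set[str], ann: AnnotationTable) -> float | None:
    """Mean pairwise Jaccard similarity over pairs with a non-empty union.

    Pairs of two unannotated proteins carry no evidence and are skipped;
    returns None when no valid pair remains.
    """
    nodes = sorted(cluster)
    sims = []
    for i in range(len(nodes)):
        ti = ann.get(nodes[i])
        for j in range(i + 1, len(nodes)):
            s = pair_similarity(ti, ann.get(nodes[j]))
            if s is not None:
                sims.append(s)
    if not sims:
        return None
    return float(np.mean(sims))


def coherence_profile(
    clustering: Clustering,
    ann: AnnotationTable,
    include_recipe: bool = True,
) -> dict[str, float]:
    """Per-cluster coherence (clusters with no valid pair omitted).

    ReCIPE-extended clusters are scored over members ∪ recipe_added.
    """
    out: dict[str, float] = {}
    for c in clustering.clusters:
        nodes = c.all_members() if include_recipe else set(c.members)
        coh = cluster_coherence(nodes, ann)
        if coh is not None:
            key = c.id if c.id is not None else min(c.members)
            out[key] = coh
    return out


def shuffled_null(
    clustering: Clustering,
    ann: AnnotationTable,
    n_perm: int = 10,
    seed: int = 0,
    nodes: list[str] | None = None,
    include_recipe: bool = True,
) -> list[dict[str, float]]:
    """Per-cluster coherences under uniformly permuted node -> GO-set maps.

    The permutation runs over ``nodes`` (default: every protein in the
    annotation table), so the multiset of annotation sets — and every
    cluster's size and degree — is preserved. One dict per permutation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    universe = sorted(nodes) if nodes is not None else sorted(ann.terms)
    rng = np.random.default_rng(seed)
    results = []
    for _ in range(n_perm):
        perm = rng.permutation(len(universe))
        mapping = {universe[i]: ann.get(universe[perm[i]]) for i in range(len(universe))}
        # nodes outside the permutation universe keep their annotation
        shuffled = AnnotationTable(terms={**ann.terms, **mapping})
        results.append(coherence_profile(clustering, shuffled, include_recipe))
    return results


def coherence_test(
    real: np.ndarray | list[float] | dict[str, float],
    null: np.ndarray | list[float] | list[dict[str, float]],
) -> tuple[float, float]:
    """One-tailed independent two-sample t-test of real > shuffled coherence."""
    if isinstance(real, dict):
        real = list(real.values())
    if isinstance(null, list) and len(null) and isinstance(null[0], dict):
        null = [v for d in null for v in d.values()]
    real = np.asarray(real, dtype=float)
    null = np.asarray(null, dtype=float)
    if real.size < 2 or null.size < 2:
        raise ValueError("need at least 2 observations per sample")
    t, p = scipy.stats.ttest_ind(real, null, alternative="greater")
    return float(t), float(p)


@dataclass
class CrossingThreshold:
    """Coherence cutoff where the real density first dominates the null."""

    threshold: float | None
    grid: np.ndarray
    real_density: np.ndarray
    null_density: np.ndarray
    diagnostic: str | None = None


@dataclass
class CoherenceResult:
    """Full output of the cluster-coherence analysis."""

    real: dict[str, float]
    null: list[dict[str, float]]
    t: float
    p: float
    crossing: CrossingThreshold


def coherence_threshold(
    real: np.ndarray | list[float] | dict[str, float],
    null: np.ndarray | list[float] | list[dict[str, float]],
    bandwidth: float | None = None,
    grid_size: int = 512,
) -> CrossingThreshold:
    """Smallest coherence above which the real density exceeds the null.

    Both samples are smoothed with a Gaussian KDE (``bandwidth`` is the KDE
    factor; default Scott's rule) on a common grid; the threshold is the
    left edge of the maximal suffix of the grid on which real > null.
    Returns None with a diagnostic when the real curve never dominates.
    """
    if isinstance(real, dict):
        real = list(real.values())
    if isinstance(null, list) and len(null) and isinstance(null[0], dict):
        null = [v for d in null for v in d.values()]
    real = np.sort(np.asarray(real, dtype=float))
    null = np.sort(np.asarray(null, dtype=float))
    lo = min(real.min(), null.min())
    hi = max(real.max(), null.max())
    pad = 0.05 * (hi - lo + 1e-12)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    try:
        kde_real = scipy.stats.gaussian_kde(real, bw_method=bandwidth)
        kde_null = scipy.stats.gaussian_kde(null, bw_method=bandwidth)
    except (np.linalg.LinAlgError, ValueError) as exc:
        return CrossingThreshold(None, grid, np.zeros_like(grid), np.zeros_like(grid),
                                 diagnostic=f"degenerate sample for KDE: {exc}")
    fr = kde_real(grid)
    fn = kde_null(grid)
    above = fr > fn
    if not above.any() or not above[-1]:
        return CrossingThreshold(None, grid, fr, fn,
                                 diagnostic="real density never dominates the null")
    # left edge of the maximal suffix where real > null
    idx = len(above) - 1
    while idx > 0 and above[idx - 1]:
        idx -= 1
    return CrossingThreshold(float(grid[idx]), grid, fr, fn)


def coherence_analysis(
    clustering: Clustering,
    ann: AnnotationTable,
    n_perm: int = 10,
    seed: int = 0,
    nodes: list[str] | None = None,
) -> CoherenceResult:
    """Convenience wrapper: profile, shuffled null, t-test and crossing point."""
    real = coherence_profile(clustering, ann)
    null = shuffled_null(clustering, ann, n_perm=n_perm, seed=seed, nodes=nodes)
    t, p = coherence_test(real, null)
    crossing = coherence_threshold(real, null)
    return CoherenceResult(real=real, null=null, t=t, p=p, crossing=crossing)


# ---------------------------------------------------------------------------
# cluster function assignment
# ---------------------------------------------------------------------------

def _support_counts(nodes: set[str], term_of) -> dict[str, int]:
    counts: dict[str, int] = {}
    for v in sorted(nodes):
        for t in term_of(v):
            counts[t] = counts.get(t, 0) + 1
    return counts


def assign_cluster_functions(
    cluster: Cluster | set[str],
    ann: AnnotationTable,
    min_support: int = 1,
) -> list[tuple[str, int]]:
    """GO terms ranked by supporting member count (desc), ties by term id.

    ReCIPE-added members count toward support.
    """
    nodes = cluster.all_members() if isinstance(cluster, Cluster) else set(cluster)
    counts = _support_counts(nodes, ann.get)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(t, s) for t, s in ranked if s >= min_support]


def slim_label(
    cluster: Cluster | set[str],
    ann: AnnotationTable,
    slim_map: dict[str, str],
    min_support: int = 3,
) -> str:
    """Most frequent slim term with support >= min_support, else "unassigned"."""
    nodes = cluster.all_members() if isinstance(cluster, Cluster) else set(cluster)

    def slim_of(v: str) -> set[str]:
        return {slim_map[t] for t in ann.get(v) if t in slim_map}

    counts = _support_counts(nodes, slim_of)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if ranked and ranked[0][1] >= min_support:
        return ranked[0][0]
    return "unassigned"


# ---------------------------------------------------------------------------
# summary cards
# ---------------------------------------------------------------------------

_SYSTEM_PROMPT = (
    "You are an expert biologist. Given a summary of a protein cluster - its "
    "size, connectivity, and most-represented GO terms - respond with a "
    "short, descriptive, human-readable name for the cluster."
)


def summary_card(
    cluster: Cluster,
    net: nx.Graph,
    ann: AnnotationTable,
    top_n: int = 5,
) -> str:
    """Deterministic text summary: size, induced edges/triangles, top terms."""
    nodes = cluster.all_members()
    sub = net.subgraph(nodes)
    n_edges = sub.number_of_edges()
    n_triangles = sum(nx.triangles(sub).values()) // 3
    top = assign_cluster_functions(cluster, ann)[:top_n]
    lines = [
        f"Cluster {cluster.id or '?'}",
        f"  proteins: {len(nodes)} ({len(cluster.members)} original"
        f" + {len(cluster.recipe_added)} re-added)",
        f"  edges: {n_edges}",
        f"  triangles: {n_triangles}",
    ]
    if top:
        lines.append("  top GO terms (term, supporting proteins):")
        lines += [f"    {t}: {s}" for t, s in top]
    else:
        lines.append("  top GO terms: none annotated")
    if cluster.slim_label is not None:
        lines.append(f"  slim label: {cluster.slim_label}")
    return "\n".join(lines)


def build_prompt(card: str) -> str:
    """Prompt string for an (external, not called here) language model."""
    return f"{_SYSTEM_PROMPT}\n\n{card}\n\nName:"


def annotate_clustering(
    clustering: Clustering,
    ann: AnnotationTable,
    net: nx.Graph,
    slim_map: dict[str, str] | None = None,
    n_perm: int = 10,
    seed: int = 0,
    min_support: int = 3,
) -> CoherenceResult:
    """Fill per-cluster coherence, functions, slim labels and summaries in place."""
    result = coherence_analysis(
        clustering, ann, n_perm=n_perm, seed=seed, nodes=sorted(net.nodes())
    )
    for c in clustering.clusters:
        key = c.id if c.id is not None else min(c.members)
        c.coherence = result.real.get(key)
        c.functions = assign_cluster_functions(c, ann)
        if slim_map is not None:
            c.slim_label = slim_label(c, ann, slim_map, min_support=min_support)
        c.summary = summary_card(c, net, ann)
    return result
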