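"""Within-cluster co-expression against a shuffled-expression null.

Pairwise association between genes is the Tukey biweight midcorrelation
(bicor), a robust correlation built from medians and median absolute
deviations; a cluster's co-expression score is the median bicor over its
gene pairs. Significance uses a paired one-tailed t-test of real
per-cluster medians against medians recomputed after permuting the gene
labels of the expression matrix (profiles themselves untouched). An
alternative cluster score is the variance explained by the first singular
component of the row-centered cluster submatrix.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
import scipy.stats

from .cluster import Clustering

logger = logging.getLogger(__name__)

__all__ = [
    "load_expression",
    "bicor",
    "cluster_coexpression",
    "coexpression_profile",
    "coexpression_test",
    "cluster_svd_score",
]


def load_expression(path) -> pd.DataFrame:
    """CSV genes x samples; first column gene id, header row sample ids."""
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()][:3].tolist()
        raise ValueError(f"duplicate gene ids in expression matrix: {dupes}")
    if df.shape[1] < 3:
        raise ValueError("expression matrix needs at least 3 samples")
    return df.astype(float)


def _biweight(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Median-centered, biweight-downweighted vector; flag False when MAD=0."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return x - np.mean(x), False
    u = (x - med) / (9.0 * mad)
    w = np.square(1.0 - np.square(u)) * (np.abs(u) < 1)
    return (x - med) * w, True


def bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation of two equal-length vectors (>= 3 samples).

    Falls back to Pearson for an argument whose MAD is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("bicor needs at least 3 samples")
    xt, x_ok = _biweight(x)
    yt, y_ok = _biweight(y)
    if not (x_ok and y_ok):  # degenerate MAD: plain Pearson on both vectors
        xt, yt = x - np.mean(x), y - np.mean(y)
    nx_ = np.linalg.norm(xt)
    ny_ = np.linalg.norm(yt)
    if nx_ == 0 or ny_ == 0:
        return 0.0
    return float(np.clip(np.dot(xt, yt) / (nx_ * ny_), -1.0, 1.0))


def cluster_coexpression(cluster: set[str], expr: pd.DataFrame) -> float | None:
    """Median pairwise bicor over cluster genes present in the matrix.

    Genes absent from the matrix are dropped (logged); None when fewer than
    one pair remains.
    """
    present = sorted(set(cluster) & set(expr.index))
    missing = len(cluster) - len(present)
    if missing:
        logger.debug("%d cluster genes absent from expression matrix", missing)
    if len(present) < 2:
        return None
    X = expr.loc[present].to_numpy()
    vals = [bicor(X[i], X[j]) for i, j in itertools.combinations(range(len(present)), 2)]
    return float(np.median(vals))


def coexpression_profile(
    clustering: Clustering,
    expr: pd.DataFrame,
    include_recipe: bool = True,
) -> dict[str, float]:
    out: dict[str, float] = {}
    for c in clustering.clusters:
        nodes = c.all_members() if include_recipe else set(c.members)
        score = cluster_coexpression(nodes, expr)
        if score is not None:
            key = c.id if c.id is not None else min(c.members)
            out[key] = score
    return out


def coexpression_test(
    clustering: Clustering,
    expr: pd.DataFrame,
    n_perm: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Paired one-tailed t-test of real vs gene-label-shuffled cluster medians.

    The null relabels rows of the expression matrix (seeded); per-cluster
    null medians are averaged over permutations and paired with the real
    medians cluster by cluster.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    real = coexpression_profile(clustering, expr)
    rng = np.random.default_rng(seed)
    genes = list(expr.index)
    null_acc: dict[str, list[float]] = {k: [] for k in real}
    for _ in range(n_perm):
        perm = rng.permutation(len(genes))
        shuffled = expr.copy()
        shuffled.index = [genes[i] for i in perm]
        prof = coexpression_profile(clustering, shuffled)
        for k in null_acc:
            if k in prof:
                null_acc[k].append(prof[k])
    keys = sorted(k for k, v in null_acc.items() if len(v) == n_perm)
    if len(keys) < 2:
        raise ValueError("need at least 2 clusters scored in both arms")
    real_arr = np.array([real[k] for k in keys])
    null_arr = np.array([np.mean(null_acc[k]) for k in keys])
    t, p = scipy.stats.ttest_rel(real_arr, null_arr, alternative="greater")
    return float(t), float(p)


def cluster_svd_score(cluster: set[str], expr: pd.DataFrame) -> float | None:
    """Variance explained by the first singular component of the submatrix.

    Rows (genes) are mean-centered; returns sigma_1^2 / sum sigma_i^2, in
    [0, 1]; None when no cluster gene is present in the matrix.
    """
    present = sorted(set(cluster) & set(expr.index))
    if not present:
        return None
    X = expr.loc[present].to_numpy()
    X = X - X.mean(axis=1, keepdims=True)
    s = np.linalg.svd(X, compute_uv=False)
    total = np.sum(np.square(s))
    if total == 0:
        return None
    return float(np.square(s[0]) / total)
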