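"""Seeded generators for networks, annotations and expression.

Every stage of the pipeline can be exercised without downloads: a
planted-partition ("stochastic block model") network stands in for a
predicted interactome, with every retained edge carrying a predictor-like
confidence score strictly above 0.5 (within-block edges drawn from a
higher-confidence band than cross-block edges). Optional hub nodes wired
across several blocks emulate the minor hubs that fragment spectral
clusters and give the reconnection step something to do. Annotation sets
are block-correlated (each block owns a term set its members receive with
``term_signal_prob``; off-block terms leak in with ``term_noise_prob``),
and expression profiles are block-correlated (shared latent profile plus
Gaussian noise). Setting signal equal to noise — or effect size to zero —
yields exact null data for calibration runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .graphio import AnnotationTable

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticSpec",
    "generate_network",
    "generate_annotations",
    "generate_expression",
    "write_synthetic_inputs",
]

_AMINO = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Defaults emulate a ~1000-protein predicted interactome: around 22
    blocks of 10-80 proteins, dense within-block wiring (p_in = 0.4) over
    sparse background (p_out = 0.01), 20 cross-block hubs, 6 GO terms per
    block with strong signal (0.8) over light noise (0.05), and 24
    expression samples at unit effect size with noise sd 0.5.
    """

    blocks: int = 22
    block_sizes: list[int] | None = None  # drawn uniformly in [10, 80] if None
    block_size_range: tuple[int, int] = (10, 80)
    p_in: float = 0.4
    p_out: float = 0.01
    hub_count: int = 20
    hub_degree: int = 12
    score_within: tuple[float, float] = (0.70, 0.99)
    score_between: tuple[float, float] = (0.51, 0.90)
    terms_per_block: int = 6
    term_signal_prob: float = 0.8
    term_noise_prob: float = 0.05
    n_samples: int = 24
    effect_size: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_in, self.p_out, self.term_signal_prob, self.term_noise_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")

    def resolve_block_sizes(self, rng: np.random.Generator) -> list[int]:
        if self.block_sizes is not None:
            return list(self.block_sizes)
        lo, hi = self.block_size_range
        return [int(s) for s in rng.integers(lo, hi + 1, size=self.blocks)]


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, stream]))


def generate_network(spec: SyntheticSpec) -> tuple[nx.Graph, dict[str, int]]:
    """Planted-partition network with predictor-like edge scores.

    Returns the graph and the planted labels (block index per node; hubs
    carry label -1). Node ids are ``p0000``-style, hubs ``h00``-style.
    """
    rng = _rng(spec, 0)
    sizes = spec.resolve_block_sizes(rng)
    labels: dict[str, int] = {}
    nodes: list[str] = []
    for b, size in enumerate(sizes):
        for _ in range(size):
            v = f"p{len(nodes):05d}"
            labels[v] = b
            nodes.append(v)
    net = nx.Graph()
    net.add_nodes_from(nodes)
    arr = np.array(nodes, dtype=object)
    lab = np.array([labels[v] for v in nodes])
    n = len(nodes)
    # vectorized Bernoulli over the upper triangle
    iu, ju = np.triu_indices(n, k=1)
    same = lab[iu] == lab[ju]
    p = np.where(same, spec.p_in, spec.p_out)
    keep = rng.random(p.size) < p
    lo_w, hi_w = spec.score_within
    lo_b, hi_b = spec.score_between
    scores = np.where(
        same, rng.uniform(lo_w, hi_w, p.size), rng.uniform(lo_b, hi_b, p.size)
    )
    for i, j, s in zip(iu[keep], ju[keep], scores[keep]):
        net.add_edge(arr[i], arr[j], weight=float(s))
    for h in range(spec.hub_count):
        v = f"h{h:02d}"
        labels[v] = -1
        targets = rng.choice(n, size=min(spec.hub_degree, n), replace=False)
        for t in targets:
            net.add_edge(v, arr[t], weight=float(rng.uniform(lo_b, hi_b)))
    return net, labels


def generate_annotations(
    labels: dict[str, int],
    spec: SyntheticSpec,
) -> tuple[AnnotationTable, dict[str, str]]:
    """Block-correlated GO sets plus a two-level term -> slim map.

    Block ``b`` owns ``terms_per_block`` terms; members receive each own
    term with ``term_signal_prob`` and each foreign term with
    ``term_noise_prob``. Each block's terms project to one slim term shared
    by a pair of adjacent blocks.
    """
    rng = _rng(spec, 1)
    blocks = sorted({b for b in labels.values() if b >= 0})
    term_ids = {
        b: [f"GO:{b * 100 + t:07d}" for t in range(spec.terms_per_block)]
        for b in blocks
    }
    slim_map = {
        t: f"GO:{9000000 + b // 2:07d}" for b in blocks for t in term_ids[b]
    }
    all_terms = [t for b in blocks for t in term_ids[b]]
    own = {t: b for b in blocks for t in term_ids[b]}
    terms: dict[str, set[str]] = {}
    for v in sorted(labels):
        b = labels[v]
        ts = set()
        for t in all_terms:
            p = spec.term_signal_prob if own[t] == b else spec.term_noise_prob
            if rng.random() < p:
                ts.add(t)
        terms[v] = ts
    return AnnotationTable(terms=terms, slim=slim_map), slim_map


def generate_expression(
    labels: dict[str, int],
    spec: SyntheticSpec,
) -> pd.DataFrame:
    """Genes x samples matrix: block latent profile times effect size plus noise."""
    rng = _rng(spec, 2)
    genes = sorted(labels)
    blocks = sorted({b for b in labels.values() if b >= 0})
    latent = {b: rng.normal(size=spec.n_samples) for b in blocks}
    rows = []
    for g in genes:
        b = labels[g]
        base = spec.effect_size * latent[b] if b >= 0 else np.zeros(spec.n_samples)
        rows.append(base + rng.normal(scale=spec.noise_sd, size=spec.n_samples)
                    if spec.noise_sd > 0 else base.copy())
    df = pd.DataFrame(
        rows, index=genes, columns=[f"s{i:02d}" for i in range(spec.n_samples)]
    )
    df.index.name = "gene"
    return df


def write_synthetic_inputs(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Materialize a full set of pipeline inputs (TSV/CSV/FASTA) on disk."""
    from . import graphio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net, labels = generate_network(spec)
    ann, slim_map = generate_annotations(labels, spec)
    expr = generate_expression(labels, spec)

    paths = {
        "network": outdir / "edges.tsv",
        "annotations": outdir / "annotations.tsv",
        "slim": outdir / "go_slim.tsv",
        "expression": outdir / "expression.csv",
        "fasta": outdir / "proteins.fasta",
        "labels": outdir / "labels.tsv",
    }
    graphio.write_network(net, paths["network"])
    graphio.write_annotations(ann, paths["annotations"])
    with open(paths["slim"], "w") as fh:
        for t in sorted(slim_map):
            fh.write(f"{t}\t{slim_map[t]}\n")
    expr.to_csv(paths["expression"])
    rng = _rng(spec, 3)
    with open(paths["fasta"], "w") as fh:
        for v in sorted(labels):
            length = int(rng.integers(40, 900))
            seq = "".join(rng.choice(_AMINO, size=length))
            fh.write(f">{v}\n")
            for i in range(0, length, 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(paths["labels"], "w") as fh:
        for v in sorted(labels):
            fh.write(f"{v}\t{labels[v]}\n")
    return paths
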