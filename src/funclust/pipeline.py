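"""End-to-end orchestration: load/filter -> DSD -> similarity -> clustering
-> reconnection -> annotation/coherence -> cluster graph -> co-expression.

The configuration is a flat YAML mapping validated against
:class:`PipelineConfig`; every stage parameter has the pipeline's default
and overrides are logged. All artifacts are stamped with a hash of the
resolved configuration and the seed, and identical config + seed reproduce
byte-identical cluster JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotate, clustergraph, coexpress, dsd, graphio
from .cluster import ClusteringParams, hierarchical_cluster
from .recipe import RecipeParams, reconnect

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "config_hash", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and its inputs."""


@dataclass
class PipelineConfig:
    # inputs
    network_tsv: str = ""
    fasta: str | None = None
    annotations_tsv: str | None = None
    slim_tsv: str | None = None
    expression_csv: str | None = None
    outdir: str = "funclust_out"
    # stage parameters (pipeline defaults)
    score_threshold: float = 0.5
    min_len: int = 50
    max_len: int = 800
    weighted: bool = True
    rbf_bandwidth: float | str = "auto"
    K: int = 500
    D: int = 20
    M: int = 3
    connect_ratio: float = 0.10
    sc_threshold: float = 0.75
    max_added: int = 20
    t: int = 10
    slim_min_support: int = 3
    n_perm: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML mapping, apply defaults, and log every override."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise PipelineError(f"config {path}: expected a mapping")
    defaults = PipelineConfig()
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError(f"config {path}: unknown keys {sorted(unknown)}")
    for key, value in raw.items():
        if getattr(defaults, key) != value:
            logger.info("config override: %s = %r", key, value)
    return PipelineConfig(**raw)


def config_hash(config: PipelineConfig) -> str:
    """Hash of the scientific configuration (the output location is excluded)."""
    d = config.to_dict()
    d.pop("outdir", None)
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _validate(config: PipelineConfig) -> None:
    if not config.network_tsv:
        raise PipelineError("config: network_tsv is required")
    for name in ("network_tsv", "fasta", "annotations_tsv", "slim_tsv",
                 "expression_csv"):
        value = getattr(config, name)
        if value and not Path(value).exists():
            raise PipelineError(f"config: {name} file not found: {value}")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every configured stage; returns the paths of written artifacts."""
    _validate(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config_hash(config), "seed": config.seed}

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("funclust")
    root.addHandler(handler)
    artifacts: dict[str, Path] = {"run_log": log_path}
    try:
        # --- load and filter -------------------------------------------------
        stage = "load_network"
        net = graphio.load_network(
            config.network_tsv, score_threshold=config.score_threshold
        )
        if config.fasta:
            stage = "filter_proteins"
            kept = {
                r.id
                for r in graphio.filter_proteins(
                    config.fasta, config.min_len, config.max_len
                )
            }
            net = net.subgraph(set(net.nodes()) & kept).copy()
        stage = "prune"
        net = dsd.prune_network(net, min_component_size=config.M)
        if net.number_of_nodes() == 0:
            raise PipelineError("network is empty after filtering")
        logger.info(
            "network: %d nodes, %d edges", net.number_of_nodes(), net.number_of_edges()
        )
        graphio.export_degree_histogram(net, outdir / "degree_histogram.tsv")
        artifacts["degree_histogram"] = outdir / "degree_histogram.tsv"

        # --- DSD and similarity ---------------------------------------------
        stage = "dsd"
        dmat = dsd.dsd_converged(net, weighted=config.weighted)
        stage = "similarity"
        S = dsd.rbf_similarity(dmat, bandwidth=config.rbf_bandwidth)

        # --- clustering and reconnection ------------------------------------
        stage = "cluster"
        clustering = hierarchical_cluster(
            S,
            dmat.nodes,
            ClusteringParams(K=config.K, D=config.D, M=config.M, seed=config.seed),
        )
        logger.info("retained %d clusters", len(clustering))
        stage = "recipe"
        clustering, recipe_report = reconnect(
            net,
            clustering,
            RecipeParams(
                connect_ratio=config.connect_ratio,
                sc_threshold=config.sc_threshold,
                max_added=config.max_added,
            ),
        )

        # --- annotation and coherence ---------------------------------------
        coherence_result = None
        slim_map = None
        if config.annotations_tsv:
            stage = "annotate"
            ann = graphio.load_annotations(config.annotations_tsv)
            if config.slim_tsv:
                slim_map = graphio.load_slim_map(config.slim_tsv)
            coherence_result = annotate.annotate_clustering(
                clustering,
                ann,
                net,
                slim_map=slim_map,
                n_perm=config.n_perm,
                seed=config.seed,
                min_support=config.slim_min_support,
            )
            report = {
                "t": coherence_result.t,
                "p": coherence_result.p,
                "coherence_threshold": coherence_result.crossing.threshold,
                "threshold_diagnostic": coherence_result.crossing.diagnostic,
                "n_clusters_scored": len(coherence_result.real),
                "mean_real": sum(coherence_result.real.values())
                / max(len(coherence_result.real), 1),
                **stamp,
            }
            path = outdir / "coherence_report.json"
            path.write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
            artifacts["coherence_report"] = path

            cards = "\n\n".join(c.summary or "" for c in clustering.clusters)
            (outdir / "summary_cards.txt").write_text(cards + "\n")
            artifacts["summary_cards"] = outdir / "summary_cards.txt"

        # --- clusters JSON ---------------------------------------------------
        stage = "write_clusters"
        clustering.params.update(stamp)
        clustering.params["recipe"] = {
            cid: {"reason": o.reason, "final_sc": o.final_sc, "added": len(o.added)}
            for cid, o in sorted(recipe_report.items())
        }
        clusters_path = outdir / "clusters.json"
        graphio.write_clusters(clustering, clusters_path)
        artifacts["clusters"] = clusters_path

        # --- cluster graph ---------------------------------------------------
        stage = "cluster_graph"
        cg = clustergraph.build_cluster_graph(net, clustering, t=config.t)
        clustergraph.export_cluster_graph(
            cg, outdir / "cluster_graph.edges.tsv", outdir / "cluster_graph.nodes.tsv"
        )
        artifacts["cluster_graph_edges"] = outdir / "cluster_graph.edges.tsv"
        artifacts["cluster_graph_nodes"] = outdir / "cluster_graph.nodes.tsv"
        ranking = clustergraph.rank_bridge_clusters(cg)
        with open(outdir / "bridge_ranking.tsv", "w") as fh:
            fh.write("cluster\tbetweenness\n")
            for cid, bc in ranking:
                fh.write(f"{cid}\t{bc:.6g}\n")
        artifacts["bridge_ranking"] = outdir / "bridge_ranking.tsv"

        # --- co-expression ---------------------------------------------------
        if config.expression_csv:
            stage = "coexpress"
            expr = coexpress.load_expression(config.expression_csv)
            tstat, p = coexpress.coexpression_test(
                clustering, expr, n_perm=config.n_perm, seed=config.seed
            )
            profile = coexpress.coexpression_profile(clustering, expr)
            svd_scores = {
                c.id: coexpress.cluster_svd_score(c.all_members(), expr)
                for c in clustering.clusters
            }
            report = {
                "t": tstat,
                "p": p,
                "n_clusters_scored": len(profile),
                "median_bicor": profile,
                "svd_score": svd_scores,
                **stamp,
            }
            path = outdir / "coexpression_report.json"
            path.write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
            artifacts["coexpression_report"] = path
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return artifacts
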