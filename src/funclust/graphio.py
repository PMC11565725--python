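"""Readers, writers and filters for the pipeline's external formats.

Covers: FASTA length filtering of a proteome, enumeration of candidate
protein pairs, the 3-column TSV edge-list dialect emitted by sequence-based
interaction predictors (kept edges require score strictly above a
threshold, default 0.5), per-protein GO annotation tables (directly or
aggregated from an hmmer per-domain table plus a domain->GO map), GO->slim
maps, and a JSON dialect for clusterings.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from Bio import SeqIO

from .cluster import Cluster, Clustering

logger = logging.getLogger(__name__)

__all__ = [
    "GraphIOError",
    "ProteinRecord",
    "AnnotationTable",
    "filter_proteins",
    "enumerate_candidate_pairs",
    "keep_set_from_terms",
    "load_network",
    "write_network",
    "load_annotations",
    "write_annotations",
    "load_slim_map",
    "load_domain_table",
    "write_clusters",
    "read_clusters",
    "degree_histogram",
    "export_degree_histogram",
]


class GraphIOError(ValueError):
    """Malformed input file or schema violation."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier and its sequence length in residues."""

    id: str
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise GraphIOError(f"protein {self.id!r} has non-positive length")


@dataclass
class AnnotationTable:
    """Protein -> set of GO term ids, with an optional GO -> GO-slim map."""

    terms: dict[str, set[str]]
    slim: dict[str, str] | None = None

    def get(self, protein: str) -> set[str]:
        return self.terms.get(protein, set())

    def slim_terms(self, protein: str) -> set[str]:
        """Project a protein's terms through the slim map (unmapped terms drop)."""
        if self.slim is None:
            raise ValueError("no slim map attached to this annotation table")
        return {self.slim[t] for t in self.get(protein) if t in self.slim}

    def __len__(self) -> int:
        return len(self.terms)


# ---------------------------------------------------------------------------
# proteome filtering and candidate pairs
# ---------------------------------------------------------------------------

def filter_proteins(
    fasta: str | Path | Iterable,
    min_len: int = 50,
    max_len: int = 800,
) -> list[ProteinRecord]:
    """Keep proteins whose length lies in [min_len, max_len], in input order.

    ``fasta`` is a path (parsed with Biopython) or an iterable of SeqRecords.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    if isinstance(fasta, (str, Path)):
        records = SeqIO.parse(str(fasta), "fasta")
    else:
        records = iter(fasta)
    out: list[ProteinRecord] = []
    seen: set[str] = set()
    try:
        for rec in records:
            if not rec.id:
                raise GraphIOError("FASTA record with empty identifier")
            if len(rec.seq) == 0:
                raise GraphIOError(f"FASTA record {rec.id!r} has an empty sequence")
            if rec.id in seen:
                raise GraphIOError(f"duplicate FASTA identifier {rec.id!r}")
            seen.add(rec.id)
            if min_len <= len(rec.seq) <= max_len:
                out.append(ProteinRecord(id=rec.id, length=len(rec.seq)))
    except ValueError as exc:  # Biopython parse failure
        if isinstance(exc, GraphIOError):
            raise
        raise GraphIOError(f"malformed FASTA: {exc}") from exc
    return out


def enumerate_candidate_pairs(
    proteins: Sequence[str],
    keep_set: set[str] | None = None,
) -> list[tuple[str, str]]:
    """All unordered id pairs (i < j lexicographically) over proteins ∩ keep_set."""
    if len(set(proteins)) != len(proteins):
        raise GraphIOError("duplicate protein ids in candidate enumeration")
    ids = sorted(p for p in proteins if keep_set is None or p in keep_set)
    return list(itertools.combinations(ids, 2))


def keep_set_from_terms(
    ann: AnnotationTable,
    terms: Iterable[str],
    closure_tsv: str | Path | None = None,
) -> set[str]:
    """Proteins annotated with any of ``terms`` or (optionally) their descendants.

    ``closure_tsv`` rows are ``term<TAB>desc1,desc2,...`` giving the
    precomputed descendant closure of each selectable term; ontology parsing
    itself is out of scope here.
    """
    wanted = set(terms)
    if closure_tsv is not None:
        for lineno, line in enumerate(Path(closure_tsv).read_text().splitlines(), 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise GraphIOError(f"{closure_tsv}: line {lineno}: expected 2 columns")
            if parts[0] in wanted:
                wanted |= {t for t in parts[1].split(",") if t}
    return {p for p, ts in ann.terms.items() if ts & wanted}


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

def load_network(
    edge_tsv: str | Path,
    score_threshold: float = 0.5,
    header: bool = False,
) -> nx.Graph:
    """Load a 3-column ``proteinA<TAB>proteinB<TAB>score`` edge list.

    Edges with score strictly greater than ``score_threshold`` are kept with
    the score as edge weight; self-loops are dropped and duplicate /
    reversed pairs are merged by maximum score.
    """
    try:
        df = pd.read_csv(
            edge_tsv,
            sep="\t",
            header=0 if header else None,
            dtype=str,
            comment=None,
        )
    except pd.errors.EmptyDataError:
        return nx.Graph()
    if df.shape[1] < 3:
        raise GraphIOError(f"{edge_tsv}: expected 3 columns, found {df.shape[1]}")
    df = df.iloc[:, :3]
    df.columns = ["a", "b", "score"]
    offset = 2 if header else 1
    scores = pd.to_numeric(df["score"], errors="coerce")
    bad = scores.isna()
    if bad.any():
        row = int(bad.idxmax()) + offset
        raise GraphIOError(
            f"{edge_tsv}: line {row}: non-numeric score {df['score'][bad.idxmax()]!r}"
        )
    out_of_range = (scores < 0) | (scores > 1)
    if out_of_range.any():
        row = int(out_of_range.idxmax()) + offset
        raise GraphIOError(f"{edge_tsv}: line {row}: score outside [0, 1]")
    net = nx.Graph()
    n_self = 0
    for a, b, s in zip(df["a"], df["b"], scores):
        if a == b:
            n_self += 1
            continue
        if s <= score_threshold:
            continue
        if net.has_edge(a, b):
            net[a][b]["weight"] = max(net[a][b]["weight"], float(s))
        else:
            net.add_edge(a, b, weight=float(s))
    if n_self:
        logger.info("dropped %d self-loop rows", n_self)
    return net


def write_network(net: nx.Graph, path: str | Path, header: bool = False) -> None:
    """Write an edge list in the same 3-column TSV dialect (sorted, stable)."""
    with open(path, "w") as fh:
        if header:
            fh.write("proteinA\tproteinB\tscore\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{a}\t{b}\t{net[a][b].get('weight', 1.0):.6g}\n")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def load_annotations(tsv: str | Path) -> AnnotationTable:
    """Load ``protein<TAB>GO:1,GO:2,...`` (second column may be empty)."""
    terms: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(tsv).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        protein = parts[0]
        if protein in terms:
            raise GraphIOError(f"{tsv}: line {lineno}: duplicate protein {protein!r}")
        ts = set()
        if len(parts) > 1 and parts[1]:
            ts = {t for t in parts[1].split(",") if t}
        terms[protein] = ts
    return AnnotationTable(terms=terms)


def write_annotations(ann: AnnotationTable, tsv: str | Path) -> None:
    with open(tsv, "w") as fh:
        for protein in sorted(ann.terms):
            fh.write(f"{protein}\t{','.join(sorted(ann.terms[protein]))}\n")


def load_slim_map(tsv: str | Path) -> dict[str, str]:
    """Load a GO -> GO-slim projection (``term<TAB>slim_term``)."""
    slim: dict[str, str] = {}
    for lineno, line in enumerate(Path(tsv).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise GraphIOError(f"{tsv}: line {lineno}: expected 2 columns")
        if parts[0] in slim and slim[parts[0]] != parts[1]:
            raise GraphIOError(
                f"{tsv}: line {lineno}: term {parts[0]!r} maps to two slim terms"
            )
        slim[parts[0]] = parts[1]
    return slim


def load_domain_table(
    domtbl: str | Path,
    domain_go_map: str | Path | dict[str, set[str]],
    evalue_cut: float = 1e-5,
    proteins: Iterable[str] | None = None,
) -> AnnotationTable:
    """Aggregate an hmmer per-domain table into per-protein GO sets.

    A protein's GO set is the union of the mapped GO terms of its domains
    whose independent E-value passes ``evalue_cut``. Domains absent from the
    map are skipped with a warning. ``proteins``, when given, fixes the
    universe so unmatched proteins appear with empty sets.
    """
    if isinstance(domain_go_map, (str, Path)):
        go_map: dict[str, set[str]] = {}
        for lineno, line in enumerate(Path(domain_go_map).read_text().splitlines(), 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise GraphIOError(
                    f"{domain_go_map}: line {lineno}: expected 2 columns"
                )
            go_map.setdefault(parts[0], set()).update(
                t for t in parts[1].split(",") if t
            )
    else:
        go_map = {d: set(ts) for d, ts in domain_go_map.items()}

    terms: dict[str, set[str]] = {p: set() for p in (proteins or [])}
    unknown: set[str] = set()
    for lineno, line in enumerate(Path(domtbl).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 13:
            raise GraphIOError(f"{domtbl}: line {lineno}: too few columns")
        domain, protein = fields[0], fields[3]
        try:
            ievalue = float(fields[12])
        except ValueError as exc:
            raise GraphIOError(
                f"{domtbl}: line {lineno}: non-numeric i-Evalue {fields[12]!r}"
            ) from exc
        terms.setdefault(protein, set())
        if ievalue > evalue_cut:
            continue
        if domain not in go_map:
            unknown.add(domain)
            continue
        terms[protein] |= go_map[domain]
    if unknown:
        logger.warning(
            "%d domains in the table have no GO mapping and were skipped: %s",
            len(unknown),
            ", ".join(sorted(unknown)[:5]),
        )
    return AnnotationTable(terms=terms)


# ---------------------------------------------------------------------------
# cluster JSON
# ---------------------------------------------------------------------------

def _cluster_to_json(c: Cluster) -> dict:
    return {
        "id": c.id,
        "members": sorted(c.members),
        "recipe_added": sorted(c.recipe_added),
        "coherence": c.coherence,
        "functions": [[t, int(s)] for t, s in c.functions],
        "slim_label": c.slim_label,
        "summary": c.summary,
    }


def write_clusters(clustering: Clustering, path: str | Path) -> None:
    """Serialize a clustering to JSON with a stable key and member order."""
    doc = {
        "params": clustering.params,
        "clusters": [_cluster_to_json(c) for c in clustering.clusters],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_clusters(path: str | Path) -> Clustering:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "clusters" not in doc:
        raise GraphIOError(f"{path}: not a cluster JSON document")
    clusters = []
    for entry in doc["clusters"]:
        members = set(entry.get("members", []))
        added = set(entry.get("recipe_added", []))
        if members & added:
            raise GraphIOError(
                f"{path}: cluster {entry.get('id')!r}: recipe_added overlaps members"
            )
        if not members:
            raise GraphIOError(f"{path}: cluster {entry.get('id')!r} has no members")
        clusters.append(
            Cluster(
                members=members,
                recipe_added=added,
                id=entry.get("id"),
                coherence=entry.get("coherence"),
                functions=[(t, int(s)) for t, s in entry.get("functions", [])],
                slim_label=entry.get("slim_label"),
                summary=entry.get("summary"),
            )
        )
    return Clustering(clusters=clusters, params=doc.get("params", {}))


# ---------------------------------------------------------------------------
# degree histogram
# ---------------------------------------------------------------------------

def degree_histogram(net: nx.Graph) -> pd.DataFrame:
    """Node counts per degree (rows with zero counts omitted)."""
    counts = nx.degree_histogram(net)
    rows = [(d, c) for d, c in enumerate(counts) if c > 0]
    return pd.DataFrame(rows, columns=["degree", "count"])


def export_degree_histogram(net: nx.Graph, path: str | Path) -> None:
    degree_histogram(net).to_csv(path, sep="\t", index=False)
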