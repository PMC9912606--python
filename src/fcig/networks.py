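"""Assembly of the disease, compound-target and merged C-T-P networks.

Three graphs underlie the core-ingredient analysis:

* the **disease gene regulatory network** — the protein-protein
  interaction (PPI) network induced on the pathogenic genes (genes whose
  disease-relevance score is strictly above the mean score);
* the bipartite **C-T network** linking screened ingredients (compounds)
  to their protein targets;
* the merged **C-T-P network** — all C-T edges plus every PPI edge whose
  two endpoints are drug targets or pathogenic genes.

Gene symbols are normalised by stripping whitespace and uppercasing; no
alias resolution is attempted.  Node bookkeeping uses the ``kind``
attribute (``gene`` or ``ingredient``) and edges carry a ``source``
provenance tag (``ppi`` or ``ct``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "load_ppi",
    "PathogenicGeneSet",
    "filter_pathogenic",
    "build_disease_network",
    "build_ct_network",
    "build_ctp_network",
    "degree_table",
    "network_summary",
    "write_sif",
    "write_graphml",
]


def _norm(symbol: str) -> str:
    return str(symbol).strip().upper()


def load_ppi(path, min_confidence: float | None = None) -> nx.Graph:
    """Read an undirected PPI edge list (TSV: gene_a, gene_b[, confidence]).

    Self-loops are dropped and duplicate / reversed-duplicate edges are
    collapsed.  Extra columns beyond the third are ignored; with
    ``min_confidence`` set, rows whose third column is below the cutoff
    are discarded.  Raises ``ValueError`` naming the offending line for
    rows with fewer than two columns.
    """
    graph = nx.Graph()
    n_loops = n_raw = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected >= 2 tab-separated columns")
            a, b = _norm(parts[0]), _norm(parts[1])
            if min_confidence is not None and len(parts) >= 3:
                try:
                    if float(parts[2]) < min_confidence:
                        continue
                except ValueError:
                    pass
            n_raw += 1
            if a == b:
                n_loops += 1
                continue
            graph.add_edge(a, b, source="ppi")
    if graph.number_of_edges() == 0:
        logger.warning("PPI file %s produced an empty network", path)
    nx.set_node_attributes(graph, "gene", "kind")
    logger.info(
        "loaded PPI %s: %d raw rows -> %d nodes, %d edges (%d self-loops dropped)",
        path, n_raw, graph.number_of_nodes(), graph.number_of_edges(), n_loops,
    )
    return graph


@dataclass(frozen=True)
class PathogenicGeneSet:
    """Genes whose relevance score strictly exceeds the mean score."""

    genes: frozenset
    scores: dict
    mean_score: float

    def __len__(self) -> int:
        return len(self.genes)


def filter_pathogenic(score_table: pd.DataFrame) -> PathogenicGeneSet:
    """Keep genes scored strictly above the mean of all scored genes.

    ``score_table`` needs columns ``gene`` and ``score``.  Rows with a
    non-numeric score are rejected with a warning, never silently kept.
    """
    if len(score_table) == 0:
        raise ValueError("filter_pathogenic: no scored genes")
    table = score_table.copy()
    table["gene"] = table["gene"].map(_norm)
    table["score"] = pd.to_numeric(table["score"], errors="coerce")
    bad = table["score"].isna()
    if bad.any():
        logger.warning("dropping %d rows with non-numeric scores", int(bad.sum()))
        table = table[~bad]
    if len(table) == 0:
        raise ValueError("filter_pathogenic: no numerically scored genes")
    mean_score = float(table["score"].mean())
    kept = table[table["score"] > mean_score]
    logger.info("pathogenic filter: %d of %d genes above mean %.4f", len(kept), len(table), mean_score)
    return PathogenicGeneSet(
        genes=frozenset(kept["gene"]),
        scores=dict(zip(table["gene"], table["score"])),
        mean_score=mean_score,
    )


def build_disease_network(pathogenic: PathogenicGeneSet, ppi: nx.Graph) -> nx.Graph:
    """PPI induced on the pathogenic genes; unmapped genes kept as isolates."""
    genes = set(pathogenic.genes)
    mapped = genes & set(ppi.nodes)
    net = nx.Graph(ppi.subgraph(mapped))
    net.add_nodes_from(genes - mapped)
    nx.set_node_attributes(net, "gene", "kind")
    if net.number_of_nodes() == 0:
        logger.warning("disease network is empty (no pathogenic genes)")
    logger.info(
        "disease network: %d/%d pathogenic genes mapped to PPI, %d nodes, %d edges",
        len(mapped), len(genes), net.number_of_nodes(), net.number_of_edges(),
    )
    return net


def build_ct_network(active: pd.DataFrame, target_map: pd.DataFrame) -> nx.Graph:
    """Bipartite compound-target network from screened ingredients.

    ``active`` needs an ``ingredient_id`` column; ``target_map`` needs
    ``ingredient_id`` and ``gene``.  Map rows referring to ingredients
    that did not survive screening are dropped with a warning.  Active
    ingredients with no targets remain as isolated ingredient nodes.
    """
    active_ids = set(active["ingredient_id"])
    tm = target_map.copy()
    tm["gene"] = tm["gene"].map(_norm)
    unknown = ~tm["ingredient_id"].isin(active_ids)
    if unknown.any():
        logger.warning("target map: dropping %d rows for non-active ingredients", int(unknown.sum()))
        tm = tm[~unknown]
    graph = nx.Graph()
    graph.add_nodes_from(active_ids, kind="ingredient")
    graph.add_nodes_from(tm["gene"].unique(), kind="gene")
    graph.add_edges_from(zip(tm["ingredient_id"], tm["gene"]), source="ct")
    n_ing = len(active_ids)
    mean_deg = (graph.number_of_edges() / n_ing) if n_ing else 0.0
    logger.info(
        "C-T network: %d ingredients, %d targets, %d edges (mean targets/ingredient %.2f)",
        n_ing, graph.number_of_nodes() - n_ing, graph.number_of_edges(), mean_deg,
    )
    return graph


def build_ctp_network(ct: nx.Graph, ppi: nx.Graph, pathogenic: PathogenicGeneSet) -> nx.Graph:
    """Merge the C-T network with PPI context.

    Union rule: every C-T edge, plus every PPI edge both of whose
    endpoints lie in (C-T target genes) union (pathogenic genes).
    Pathogenic genes absent from both sources are kept as isolated nodes
    so the downstream effect-space partition sees them.
    """
    targets = {n for n, k in ct.nodes(data="kind") if k == "gene"}
    scope = targets | set(pathogenic.genes)
    graph = nx.Graph(ct)
    for a, b in ppi.subgraph(scope & set(ppi.nodes)).edges:
        if not graph.has_edge(a, b):
            graph.add_edge(a, b, source="ppi")
    graph.add_nodes_from(scope - set(graph.nodes))
    for node in scope:
        graph.nodes[node]["kind"] = "gene"
    logger.info("C-T-P network: %d nodes, %d edges", graph.number_of_nodes(), graph.number_of_edges())
    return graph


def degree_table(graph: nx.Graph, kind: str | None = None) -> pd.DataFrame:
    """Per-node degree table, optionally restricted to one node class."""
    rows = [
        (node, attrs.get("kind", "gene"), graph.degree(node))
        for node, attrs in graph.nodes(data=True)
        if kind is None or attrs.get("kind") == kind
    ]
    return pd.DataFrame(rows, columns=["node", "kind", "degree"]).sort_values(
        ["degree", "node"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def network_summary(graph: nx.Graph) -> dict:
    """Node/edge counts broken down by node class and edge provenance."""
    kinds = pd.Series([k for _, k in graph.nodes(data="kind")]).value_counts().to_dict()
    sources = pd.Series([s for _, _, s in graph.edges(data="source")]).value_counts().to_dict()
    return {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "nodes_by_kind": {str(k): int(v) for k, v in sorted(kinds.items(), key=str)},
        "edges_by_source": {str(k): int(v) for k, v in sorted(sources.items(), key=str)},
    }


def write_sif(graph: nx.Graph, path) -> None:
    """Simple interaction format: node <tab> relation <tab> node."""
    with open(path, "w") as handle:
        for a, b, src in sorted(graph.edges(data="source")):
            handle.write(f"{a}\t{src or 'edge'}\t{b}\n")
        for node in sorted(nx.isolates(graph)):
            handle.write(f"{node}\n")


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def write_summary(graph: nx.Graph, path) -> None:
    Path(path).write_text(json.dumps(network_summary(graph), indent=2, sort_keys=True) + "\n")
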