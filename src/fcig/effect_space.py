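"""Potential effect space (PES) extraction and response-protein selection.

The PES is the part of the merged compound-target-PPI (C-T-P) network
where drug action can plausibly meet disease biology.  Its proteins fall
into three disjoint categories, with "direct interaction" read as graph
distance <= 1 in the protein layer (a drug target that *is* a pathogenic
gene counts as distance 0):

* **common targets** — drug targets that are pathogenic genes or direct
  PPI neighbours of pathogenic genes;
* **ingredient-specific** — drug targets with no pathogenic gene within
  distance 1;
* **disease-specific** — pathogenic genes that are not targets and have
  no drug target within distance 1.

Response (therapeutic effect) proteins are then chosen by the BD
median-split applied to the PES-induced subgraph: score every PES
protein, keep those at or above the median BD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .importance import bd_table, select_important_nodes

logger = logging.getLogger(__name__)

__all__ = ["PotentialEffectSpace", "ResponseProteinSet", "classify_pes", "select_response_proteins"]


@dataclass(frozen=True)
class PotentialEffectSpace:
    common_targets: frozenset
    ingredient_specific: frozenset
    disease_specific: frozenset
    pes_graph: nx.Graph = field(repr=False, compare=False)

    @property
    def nodes(self) -> frozenset:
        return self.common_targets | self.ingredient_specific | self.disease_specific

    def category_sizes(self) -> dict:
        return {
            "common_targets": len(self.common_targets),
            "ingredient_specific": len(self.ingredient_specific),
            "disease_specific": len(self.disease_specific),
            "total": len(self.nodes),
        }

    def category_table(self) -> pd.DataFrame:
        rows = [(g, "common") for g in self.common_targets]
        rows += [(g, "ingredient_specific") for g in self.ingredient_specific]
        rows += [(g, "disease_specific") for g in self.disease_specific]
        return pd.DataFrame(sorted(rows), columns=["gene", "category"])


def _gene_neighbors(graph: nx.Graph, node) -> set:
    if node not in graph:
        return set()
    return {n for n in graph.neighbors(node) if graph.nodes[n].get("kind", "gene") == "gene"}


def classify_pes(ctp: nx.Graph, pathogenic_genes, target_genes) -> PotentialEffectSpace:
    """Partition PES proteins into common / ingredient-specific / disease-specific.

    ``pathogenic_genes`` and ``target_genes`` are gene-symbol sets; genes
    absent from the C-T-P graph are treated as isolated.  The PES graph is
    the C-T-P subgraph induced on the union of the three categories
    (protein-protein edges only — no ingredient nodes are in the union).
    """
    pathogenic = set(pathogenic_genes)
    targets = set(target_genes)
    if not pathogenic or not targets:
        logger.warning("classify_pes: empty pathogenic or target set; PES may be degenerate")

    common = {
        t for t in targets
        if t in pathogenic or _gene_neighbors(ctp, t) & pathogenic
    }
    ingredient_specific = targets - common
    disease_specific = {
        g for g in pathogenic
        if g not in targets and not (_gene_neighbors(ctp, g) & targets)
    }
    union = common | ingredient_specific | disease_specific
    pes_graph = nx.Graph(ctp.subgraph(union & set(ctp.nodes)))
    pes_graph.add_nodes_from(union - set(pes_graph.nodes))
    nx.set_node_attributes(pes_graph, "gene", "kind")
    space = PotentialEffectSpace(
        frozenset(common), frozenset(ingredient_specific), frozenset(disease_specific), pes_graph
    )
    logger.info("PES categories: %s", space.category_sizes())
    return space


@dataclass(frozen=True)
class ResponseProteinSet:
    proteins: frozenset
    bd_table: pd.DataFrame = field(repr=False, compare=False)
    threshold: float = float("nan")


def select_response_proteins(
    space: PotentialEffectSpace,
    ordered_pairs: bool = False,
    full_graph: nx.Graph | None = None,
) -> ResponseProteinSet:
    """Median-split BD selection of response proteins inside the PES.

    Scores are computed on the PES-induced subgraph by default; pass
    ``full_graph`` to score on a larger network instead (the selection is
    still restricted to PES members).  A single-node PES selects that
    node; an all-isolated PES has every BD equal to 0 and therefore
    selects everything (degenerate, warned).
    """
    graph = space.pes_graph if full_graph is None else full_graph.subgraph(space.nodes)
    if graph.number_of_nodes() == 0:
        logger.warning("select_response_proteins: empty PES")
        return ResponseProteinSet(frozenset(), bd_table(graph))
    table = bd_table(graph, ordered_pairs=ordered_pairs)
    if (table["bd"] == 0).all():
        logger.warning("select_response_proteins: all BD scores are 0; selection is degenerate")
    picked = select_important_nodes(table)
    table = table.assign(selected=table["node"].isin(picked.selected))
    return ResponseProteinSet(frozenset(picked.selected), table, picked.threshold_value)
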