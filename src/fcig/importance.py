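"""Betweenness-degree (BD) hybrid node importance and median-split selection.

The BD score of a node *h* in an undirected simple graph combines local
connectivity with shortest-path control:

    BD_h = sqrt(T_h * btw_h)

where ``T_h`` is the degree of *h* and ``btw_h`` is the unnormalised
(Freeman) betweenness of *h*: the sum over unordered node pairs {i, k},
both distinct from *h*, of the fraction of shortest i-k paths that pass
through *h*.  Hubs that also broker many shortest paths score highest;
leaves and isolated nodes score exactly 0.

Important nodes are then chosen by a median split: scores are sorted
ascending, the threshold is the middle value (odd node count) or the mean
of the two middle values (even count), and every node whose BD is greater
than or equal to the threshold is selected, ties included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "betweenness_fraction_sum",
    "bd_score",
    "bd_table",
    "median_split_threshold",
    "select_important_nodes",
    "ImportantNodeSet",
]


def _betweenness_all(graph: nx.Graph, ordered_pairs: bool = False) -> dict:
    """Unnormalised betweenness for every node.

    Pairs in different components contribute 0 (there is no shortest path
    to fractionate).  With ``ordered_pairs=True`` each pair {i, k} is
    counted twice — (i, k) and (k, i) — which exactly doubles every value.
    """
    btw = nx.betweenness_centrality(graph, normalized=False)
    if ordered_pairs:
        btw = {v: 2.0 * b for v, b in btw.items()}
    return btw


def betweenness_fraction_sum(graph: nx.Graph, node, ordered_pairs: bool = False) -> float:
    """Sum of shortest-path fractions through ``node``.

    Raises ``KeyError`` if the node is not in the graph.
    """
    if node not in graph:
        raise KeyError(f"node {node!r} not in graph")
    return _betweenness_all(graph, ordered_pairs=ordered_pairs)[node]


def bd_score(graph: nx.Graph, node, ordered_pairs: bool = False) -> float:
    """BD score sqrt(degree x betweenness-fraction sum) for one node."""
    btw = betweenness_fraction_sum(graph, node, ordered_pairs=ordered_pairs)
    return float(np.sqrt(graph.degree(node) * btw))


def bd_table(graph: nx.Graph, ordered_pairs: bool = False) -> pd.DataFrame:
    """Score every node of ``graph``.

    Returns a DataFrame with columns ``node, degree, btw, bd, rank``.
    ``rank`` is the 1-based position in the ascending BD sort (ties broken
    by node label so the table is reproducible across platforms).
    """
    btw = _betweenness_all(graph, ordered_pairs=ordered_pairs)
    rows = [
        (node, graph.degree(node), btw[node], float(np.sqrt(graph.degree(node) * btw[node])))
        for node in graph.nodes
    ]
    table = pd.DataFrame(rows, columns=["node", "degree", "btw", "bd"])
    table = table.sort_values(["bd", "node"], kind="mergesort").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


@dataclass(frozen=True)
class ImportantNodeSet:
    """Result of the median-split selection."""

    selected: frozenset
    threshold_value: float
    table: pd.DataFrame = field(repr=False, compare=False, default=None)


def median_split_threshold(scores) -> float:
    """Threshold of the median-split rule.

    Scores sorted ascending into Y; for m = 2p+1 the threshold is the
    middle value Y_(m+1)/2, for m = 2p it is (Y_m/2 + Y_(m+2)/2) / 2.
    """
    y = np.sort(np.asarray(list(scores), dtype=float))
    m = y.size
    if m == 0:
        raise ValueError("median-split threshold of an empty score list")
    if m % 2 == 1:
        return float(y[(m - 1) // 2])
    return float((y[m // 2 - 1] + y[m // 2]) / 2.0)


def select_important_nodes(table: pd.DataFrame) -> ImportantNodeSet:
    """Select nodes with BD >= the median-split threshold (ties kept).

    ``table`` is a BD score table as produced by :func:`bd_table`.  An
    empty table yields an empty selection with a warning.
    """
    if len(table) == 0:
        logger.warning("empty BD table: selecting no nodes")
        return ImportantNodeSet(frozenset(), float("nan"), table)
    threshold = median_split_threshold(table["bd"].to_numpy())
    chosen = table.loc[table["bd"] >= threshold, "node"]
    return ImportantNodeSet(frozenset(chosen), threshold, table)
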