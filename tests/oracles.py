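"""Independent brute-force oracles used to anchor the fast implementations.

Everything here is deliberately naive: shortest paths are enumerated
explicitly and hypergeometric tails are computed by exhaustive subset
enumeration, so none of it shares code (or algorithms) with the package.
"""

from __future__ import annotations

import itertools
from collections import deque
from math import comb


def all_shortest_paths(graph, source, target) -> list:
    """Every shortest source-target path, as node tuples, by BFS layering."""
    if source == target:
        return [(source,)]
    dist = {source: 0}
    preds = {source: []}
    queue = deque([source])
    while queue:
        node = queue.popleft()
        for nbr in graph.neighbors(node):
            if nbr not in dist:
                dist[nbr] = dist[node] + 1
                preds[nbr] = [node]
                queue.append(nbr)
            elif dist[nbr] == dist[node] + 1:
                preds[nbr].append(node)
    if target not in dist:
        return []
    paths = []

    def walk(node, suffix):
        if node == source:
            paths.append((source, *suffix))
            return
        for p in preds[node]:
            walk(p, (node, *suffix))

    walk(target, ())
    return paths


def brute_betweenness_fraction_sum(graph, j) -> float:
    """Sum over unordered pairs {h, i} (both != j) of the fraction of
    shortest h-i paths with j as an interior node."""
    total = 0.0
    for h, i in itertools.combinations(graph.nodes, 2):
        if j in (h, i):
            continue
        paths = all_shortest_paths(graph, h, i)
        if not paths:
            continue
        through = sum(1 for p in paths if j in p[1:-1])
        total += through / len(paths)
    return total


def brute_bd_score(graph, node) -> float:
    return (graph.degree(node) * brute_betweenness_fraction_sum(graph, node)) ** 0.5


def brute_hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P[X >= k] by exhaustive enumeration of all n-subsets of an N-universe
    containing K marked elements (feasible for N <= ~12)."""
    universe = list(range(N))
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    assert total == comb(N, n)
    return hits / total


def reference_median_split(scores) -> tuple:
    """Piecewise median-split rule applied literally to a score list.

    Returns (threshold, number selected): sort ascending into Y; odd m
    takes Y[(m+1)/2] (1-based), even m the mean of Y[m/2], Y[m/2+1];
    select every score >= threshold.
    """
    y = sorted(scores)
    m = len(y)
    if m % 2 == 1:
        thr = y[(m + 1) // 2 - 1]
    else:
        thr = (y[m // 2 - 1] + y[m // 2]) / 2
    return thr, sum(1 for s in y if s >= thr)
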