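"""Hypergeometric gene-set enrichment and coverage/overlap validation.

Enrichment of a query gene set in an annotation term is scored with the
exact hypergeometric upper tail: with a background universe of N genes of
which K belong to the term, and a query of n genes of which k hit the
term,

    p = P[X >= k],  X ~ Hypergeometric(N, K, n).

A term is called enriched at p < alpha (0.05 by default, unadjusted;
Benjamini-Hochberg correction is available via a flag).  On top of the
per-term test the module provides the validation metrics used to compare
gene sets at the functional level:

* pathway coverage — the fraction of a reference set's enriched terms
  that are also enriched for the query set;
* Venn overlap — intersection counts of two gene sets with a reference
  (e.g. pathogenic genes) and the retention ratio between them;
* functional similarity — Jaccard index of two enriched-term sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd
from scipy.stats import hypergeom

from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "read_gmt",
    "write_gmt",
    "hypergeometric_enrich",
    "enriched_terms",
    "CoverageReport",
    "pathway_coverage",
    "venn_overlap",
    "functional_similarity",
]


def read_gmt(path) -> dict:
    """GMT reader: term <tab> description <tab> gene... -> {term: gene set}."""
    terms = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                if line.strip():
                    logger.warning("%s: line %d has no genes, skipped", path, lineno)
                continue
            terms[parts[0]] = {g.strip().upper() for g in parts[2:] if g.strip()}
    return terms


def write_gmt(terms: dict, path, description: str = "") -> None:
    with open(path, "w") as handle:
        for term, genes in sorted(terms.items()):
            handle.write("\t".join([term, description or term] + sorted(genes)) + "\n")


def hypergeometric_enrich(
    query,
    gene_sets: dict,
    background=None,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Exact upper-tail hypergeometric enrichment of ``query`` per term.

    The background defaults to the union of all genes in ``gene_sets``.
    Query genes outside the background are dropped with a warning; terms
    are intersected with the background and empty terms skipped.  Returns
    columns ``term, k, K, n, N, p`` (plus ``p_adj`` under BH adjustment)
    and the boolean ``enriched`` at ``alpha``.
    """
    if background is None:
        background = set().union(*gene_sets.values()) if gene_sets else set()
    background = set(background)
    if not background:
        raise ValueError("empty background universe")
    query = set(query)
    outside = query - background
    if outside:
        logger.warning("enrichment: %d query genes outside background dropped", len(outside))
        query &= background
    N, n = len(background), len(query)
    rows = []
    for term, genes in sorted(gene_sets.items()):
        members = set(genes) & background
        K = len(members)
        if K == 0:
            logger.warning("term %s has no background genes, skipped", term)
            continue
        k = len(query & members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, p))
    table = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if adjust and len(table):
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
        table["enriched"] = table["p_adj"] < alpha
    else:
        table["enriched"] = table["p"] < alpha
    return table


def enriched_terms(table: pd.DataFrame) -> set:
    return set(table.loc[table["enriched"], "term"])


@dataclass(frozen=True)
class CoverageReport:
    coverage: float
    query_terms: frozenset
    reference_terms: frozenset
    shared_terms: frozenset


def pathway_coverage(enriched_query, enriched_reference) -> CoverageReport:
    """Fraction of the reference's enriched terms that the query also enriches.

    Both arguments may be enrichment tables or plain term sets.  An empty
    reference makes the ratio undefined (NaN, warned).
    """
    q = enriched_terms(enriched_query) if isinstance(enriched_query, pd.DataFrame) else set(enriched_query)
    r = enriched_terms(enriched_reference) if isinstance(enriched_reference, pd.DataFrame) else set(enriched_reference)
    shared = q & r
    if not r:
        logger.warning("pathway_coverage: empty reference term set, coverage undefined")
        cov = math.nan
    else:
        cov = len(shared) / len(r)
    return CoverageReport(cov, frozenset(q), frozenset(r), frozenset(shared))


def _round_half_up_1dp(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def venn_overlap(set_a, set_b, reference) -> dict:
    """Overlap counts of two gene sets with a reference, plus retention.

    Returns ``a_in_ref``, ``b_in_ref`` and ``retention_pct`` =
    100 * |B ∩ ref| / |A ∩ ref| rounded half-up to one decimal (NaN with
    a warning when A misses the reference entirely).
    """
    a_in_ref = len(set(set_a) & set(reference))
    b_in_ref = len(set(set_b) & set(reference))
    if a_in_ref == 0:
        logger.warning("venn_overlap: reference disjoint from set A, ratio undefined")
        ratio = math.nan
    else:
        ratio = _round_half_up_1dp(100.0 * b_in_ref / a_in_ref)
    return {"a_in_ref": a_in_ref, "b_in_ref": b_in_ref, "retention_pct": ratio}


def functional_similarity(enriched_a, enriched_b) -> float:
    """Jaccard index of two enriched-term sets (0 when both are empty)."""
    a = enriched_terms(enriched_a) if isinstance(enriched_a, pd.DataFrame) else set(enriched_a)
    b = enriched_terms(enriched_b) if isinstance(enriched_b, pd.DataFrame) else set(enriched_b)
    union = a | b
    if not union:
        logger.warning("functional_similarity: both term sets empty, similarity defined as 0")
        return 0.0
    return len(a & b) / len(union)
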