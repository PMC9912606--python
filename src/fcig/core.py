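"""Contribution-index ranking and functional core ingredient group (FCIG).

Each screened ingredient is scored by how much node importance it reaches
inside the response-protein set: the default contribution index (CI) of
ingredient *i* is the sum of BD scores of its targets that are response
proteins.  Ingredients are ranked by descending CI; the FCIG is the
minimal prefix whose cumulative contribution rate (CI normalised to sum
to 1) reaches the cutoff, 0.90 by default — the published analogue
selects the prefix that first crosses 90%.

Alternative CI definitions are available through ``ci_mode``:

* ``"bd_sum"`` (default) — sum of response-protein BD scores;
* ``"count"``  — number of response-protein targets;
* ``"bd_fraction"`` — bd_sum divided by the total BD of the response set
  (a rescaling of bd_sum; identical ranking).
"""

from __future__ import annotations

import logging
import math

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["contribution_index", "cumulative_fcig", "recover_planted_core"]

CI_MODES = ("bd_sum", "count", "bd_fraction")


def contribution_index(
    target_map: pd.DataFrame,
    response_proteins,
    bd_scores,
    ci_mode: str = "bd_sum",
    ingredient_ids=None,
) -> pd.Series:
    """Per-ingredient contribution index.

    ``target_map`` has columns ``ingredient_id`` and ``gene``;
    ``bd_scores`` maps gene -> BD score (only response proteins are
    consulted).  With ``ingredient_ids`` given, map rows for unknown
    ingredients are warned about and skipped, and every listed ingredient
    appears in the result (CI = 0 when it has no response-protein
    target).
    """
    if ci_mode not in CI_MODES:
        raise ValueError(f"unknown ci_mode {ci_mode!r}; expected one of {CI_MODES}")
    response = set(response_proteins)
    bd = dict(bd_scores)
    tm = target_map[["ingredient_id", "gene"]].drop_duplicates()
    if ingredient_ids is not None:
        known = set(ingredient_ids)
        unknown = ~tm["ingredient_id"].isin(known)
        if unknown.any():
            logger.warning(
                "contribution_index: skipping %d map rows for unknown ingredients",
                int(unknown.sum()),
            )
            tm = tm[~unknown]
    hits = tm[tm["gene"].isin(response)]
    if ci_mode == "count":
        ci = hits.groupby("ingredient_id")["gene"].size().astype(float)
    else:
        ci = hits.groupby("ingredient_id")["gene"].agg(lambda genes: sum(bd.get(g, 0.0) for g in genes))
        if ci_mode == "bd_fraction":
            total = sum(bd.get(g, 0.0) for g in response)
            ci = ci / total if total > 0 else ci * 0.0
    universe = sorted(known) if ingredient_ids is not None else sorted(tm["ingredient_id"].unique())
    ci = ci.reindex(universe, fill_value=0.0)
    ci.index.name = "ingredient_id"
    ci.name = "ci"
    return ci


def cumulative_fcig(ci: pd.Series, threshold: float = 0.90) -> pd.DataFrame:
    """Descending-CI ranking with cumulative cutoff.

    Returns a DataFrame (``ingredient_id, ci, rate, cum_rate, fcig``)
    sorted by descending CI, ties broken lexicographically by ingredient
    id so the ranking is reproducible.  The FCIG flag marks the minimal
    prefix whose cumulative rate reaches ``threshold``.  Raises when no
    ingredient contributes.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold!r}")
    total = float(ci.sum())
    if total <= 0:
        raise ValueError("no contributing ingredients (all CI values are 0)")
    table = ci.rename("ci").rename_axis("ingredient_id").reset_index()
    table = table.sort_values(
        ["ci", "ingredient_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rate"] = table["ci"] / total
    table["cum_rate"] = table["rate"].cumsum()
    cutoff_pos = int((table["cum_rate"] >= threshold - 1e-12).idxmax())
    table["fcig"] = table.index <= cutoff_pos
    logger.info(
        "FCIG: %d of %d ingredients reach cumulative rate %.4f (threshold %.2f)",
        cutoff_pos + 1, len(table), table.loc[cutoff_pos, "cum_rate"], threshold,
    )
    return table


def recover_planted_core(fcig_result: pd.DataFrame, truth) -> tuple[float, float]:
    """Precision and recall of the FCIG against a planted core.

    ``truth`` is a GroundTruth (``core_ingredient_ids`` attribute) or any
    iterable of planted ingredient ids.  An empty FCIG gives NaN
    precision with a warning; an empty planted set gives NaN recall.
    """
    planted = set(getattr(truth, "core_ingredient_ids", truth))
    selected = set(fcig_result.loc[fcig_result["fcig"], "ingredient_id"])
    overlap = len(selected & planted)
    if not selected:
        logger.warning("recover_planted_core: empty FCIG, precision undefined")
        precision = math.nan
    else:
        precision = overlap / len(selected)
    recall = overlap / len(planted) if planted else math.nan
    return precision, recall
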