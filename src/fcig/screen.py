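"""ADME screening of herbal ingredients and shared/specific analysis.

Candidate ingredients are filtered on three absorption/distribution
properties as retrieved from TCMSP-style resources:

* **OB** — oral bioavailability (%), kept when >= 30;
* **Caco-2** — intestinal permeability surrogate (dimensionless transport
  rate, may be negative), kept when > -0.4;
* **DL** — drug-likeness in [0, 1], kept when >= 0.18.

Ingredients known from chemical analysis to be present at high content
and high bioactivity may be whitelisted: a whitelisted ingredient is
retained regardless of its ADME values, so the screened set is exactly
(ADME passes) union (whitelist intersect input).

The module also reports which retained ingredients are shared by two or
more herbs of a formula and which are specific to a single herb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AdmeThresholds",
    "read_ingredients",
    "read_whitelist",
    "load_dtt_ingredients",
    "adme_screen",
    "shared_ingredients",
    "specific_ingredients",
]

_REQUIRED = ["herb", "ingredient_id", "name", "ob", "caco2", "dl"]


@dataclass(frozen=True)
class AdmeThresholds:
    """Screening cutoffs. OB and DL are inclusive bounds, Caco-2 exclusive."""

    ob_min: float = 30.0
    caco2_min: float = -0.4
    dl_min: float = 0.18

    def __post_init__(self):
        if self.ob_min < 0:
            raise ValueError("ob_min must be nonnegative")


def read_ingredients(path) -> pd.DataFrame:
    """Read an ingredient CSV with columns herb, ingredient_id, name, ob, caco2, dl."""
    table = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return table[_REQUIRED]


def load_dtt_ingredients() -> pd.DataFrame:
    """Bundled ADME table of the nine-herb Di-Tan decoction (TCMSP values)."""
    with resources.files("fcig.data").joinpath("dtt_ingredients.csv").open() as handle:
        return pd.read_csv(handle)


def read_whitelist(path) -> set:
    """Plain-text whitelist, one ingredient id per line; '#' comments allowed."""
    ids = set()
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line)
    return ids


def adme_screen(
    records: pd.DataFrame,
    thresholds: AdmeThresholds | None = None,
    whitelist_ids=(),
) -> pd.DataFrame:
    """Retain ingredients passing ADME cutoffs or named on the whitelist.

    Duplicate (herb, ingredient_id) rows are collapsed first.  Rows with
    a missing or non-numeric ADME field are rejected with a warning
    unless whitelisted.  The result preserves input order and carries a
    ``pass_reason`` column ('adme' or 'whitelist').
    """
    thresholds = thresholds or AdmeThresholds()
    whitelist_ids = set(whitelist_ids)
    table = records.drop_duplicates(subset=["herb", "ingredient_id"]).copy()
    for col in ("ob", "caco2", "dl"):
        table[col] = pd.to_numeric(table[col], errors="coerce")
    incomplete = table[["ob", "caco2", "dl"]].isna().any(axis=1)
    if incomplete.any():
        logger.warning(
            "adme_screen: %d rows with missing/non-numeric ADME fields rejected "
            "from ADME evaluation", int(incomplete.sum()),
        )
    adme_pass = (
        ~incomplete
        & (table["ob"] >= thresholds.ob_min)
        & (table["caco2"] > thresholds.caco2_min)
        & (table["dl"] >= thresholds.dl_min)
    )
    wl = table["ingredient_id"].isin(whitelist_ids)
    kept = table[adme_pass | wl].copy()
    kept["pass_reason"] = ["adme" if a else "whitelist" for a in adme_pass[adme_pass | wl]]
    logger.info(
        "adme_screen: %d of %d rows retained (%d ADME pass, %d whitelist-only)",
        len(kept), len(table), int(adme_pass.sum()), int((wl & ~adme_pass).sum()),
    )
    return kept.reset_index(drop=True)


def _herbs_per_ingredient(active: pd.DataFrame) -> pd.DataFrame:
    pairs = active[["ingredient_id", "herb"]].drop_duplicates()
    grouped = pairs.groupby("ingredient_id")["herb"].agg(sorted)
    names = active.drop_duplicates("ingredient_id").set_index("ingredient_id")["name"]
    out = pd.DataFrame({
        "ingredient_id": grouped.index,
        "name": names.reindex(grouped.index).to_numpy(),
        "herbs": [";".join(h) for h in grouped],
        "n_herbs": [len(h) for h in grouped],
    }).reset_index(drop=True)
    return out.sort_values("ingredient_id", kind="mergesort").reset_index(drop=True)


def shared_ingredients(active: pd.DataFrame, min_herbs: int = 2) -> pd.DataFrame:
    """Ingredients appearing under at least ``min_herbs`` distinct herbs.

    Default 2 matches the published shared-ingredient tables, which list
    two-herb entries despite a "more than two" phrasing; pass
    ``min_herbs=3`` for the stricter reading.
    """
    table = _herbs_per_ingredient(active)
    out = table[table["n_herbs"] >= min_herbs].reset_index(drop=True)
    logger.info("shared_ingredients: %d ingredients in >= %d herbs", len(out), min_herbs)
    return out


def specific_ingredients(active: pd.DataFrame) -> pd.DataFrame:
    """Ingredients found in exactly one herb (complement of the shared set)."""
    table = _herbs_per_ingredient(active)
    return table[table["n_herbs"] == 1].reset_index(drop=True)
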