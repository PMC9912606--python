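"""Synthetic benchmark generator with a planted core ingredient group.

Emulates the five inputs of the core-ingredient pipeline so every stage
can run, and be validated against ground truth, without any database
downloads:

1. a scale-free protein-protein interaction network (preferential
   attachment, because real PPI degree distributions are heavy-tailed and
   the BD score's behaviour depends on hubs existing);
2. per-gene disease relevance scores — Gaussian background plus a fixed
   positive shift for a designated pathogenic subset, so the above-mean
   filter recovers the subset with high probability;
3. a multi-herb ingredient table with OB / Caco-2 / DL values, a planted
   core subgroup guaranteed to pass the ADME screen;
4. an ingredient-to-target map in which planted core ingredients have
   many targets drawn preferentially from pathogenic genes and their
   network neighbours (controlled by ``core_target_bias``), while filler
   ingredients have few, uniformly random targets;
5. pathway annotations (GMT) built as random-walk neighbourhoods around
   seed genes, so gene-set enrichment has genuine signal.

A single global seed drives an ordered sequence of per-stage substreams
(numpy ``SeedSequence`` spawn keys), so adding a later stage never
perturbs the output of an earlier one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_ppi",
    "generate_disease_scores",
    "generate_formula",
    "generate_pathways",
    "generate_all",
    "write_inputs",
]

# substream indices; append only, never reorder
_STAGE_PPI = 0
_STAGE_SCORES = 1
_STAGE_FORMULA = 2
_STAGE_PATHWAYS = 3


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study conditions.

    Defaults give a 300-gene interactome with 60 pathogenic genes and a
    3-herb, 30-ingredient formula carrying a 5-ingredient planted core.
    Core ingredients get ~5x more targets than fillers, mirroring the
    spread between hub ingredients and the average in real
    compound-target networks.
    """

    n_genes: int = 300
    attach_m: int = 3
    n_pathogenic: int = 60
    score_mean: float = 5.0
    score_sd: float = 1.5
    score_shift: float = 5.0
    n_herbs: int = 3
    ingredients_per_herb: int = 10
    planted_core_size: int = 5
    targets_per_core_ingredient: int = 20
    targets_per_filler_ingredient: int = 4
    core_target_bias: float = 0.9
    n_pathways: int = 30
    pathway_size: int = 15
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_genes": self.n_genes,
            "attach_m": self.attach_m,
            "n_pathogenic": self.n_pathogenic,
            "n_herbs": self.n_herbs,
            "ingredients_per_herb": self.ingredients_per_herb,
            "planted_core_size": self.planted_core_size,
            "targets_per_core_ingredient": self.targets_per_core_ingredient,
            "targets_per_filler_ingredient": self.targets_per_filler_ingredient,
            "n_pathways": self.n_pathways,
            "pathway_size": self.pathway_size,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ValueError(f"config field {name} must be a positive integer, got {value!r}")
        if not 0.0 <= self.core_target_bias <= 1.0:
            raise ValueError(f"config field core_target_bias must lie in [0, 1], got {self.core_target_bias!r}")
        if self.n_genes < self.attach_m + 1:
            raise ValueError("config field n_genes must exceed attach_m")
        if self.n_pathogenic > self.n_genes:
            raise ValueError("config field n_pathogenic exceeds n_genes")
        if self.planted_core_size > self.n_herbs * self.ingredients_per_herb:
            raise ValueError("config field planted_core_size exceeds the ingredient count")
        if self.score_sd <= 0:
            raise ValueError("config field score_sd must be positive")

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-local random stream derived from the global seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stage,)))


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    core_ingredient_ids: set = field(default_factory=set)
    pathogenic_genes: set = field(default_factory=set)
    pathway_membership: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "core_ingredient_ids": sorted(self.core_ingredient_ids),
            "pathogenic_genes": sorted(self.pathogenic_genes),
            "pathway_membership": {t: sorted(g) for t, g in sorted(self.pathway_membership.items())},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            core_ingredient_ids=set(payload["core_ingredient_ids"]),
            pathogenic_genes=set(payload["pathogenic_genes"]),
            pathway_membership={t: set(g) for t, g in payload["pathway_membership"].items()},
        )


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def generate_ppi(config: SyntheticConfig) -> nx.Graph:
    """Scale-free PPI stand-in: preferential-attachment growth.

    Connected, undirected, simple; ``attach_m`` edges per arriving node,
    hence m * (n - m) edges in total (the initial m nodes carry none).
    """
    rng = config.rng(_STAGE_PPI)
    raw = nx.barabasi_albert_graph(config.n_genes, config.attach_m, seed=rng)
    graph = nx.relabel_nodes(raw, {i: _gene_name(i) for i in raw.nodes})
    nx.set_node_attributes(graph, "gene", "kind")
    nx.set_edge_attributes(graph, "ppi", "source")
    return graph


def generate_disease_scores(config: SyntheticConfig, network: nx.Graph) -> pd.DataFrame:
    """Relevance scores: Normal background, shifted pathogenic subset.

    The ``n_pathogenic`` designated genes are grown as a few random-walk
    modules (disease genes cluster in interactome neighbourhoods rather
    than scattering uniformly or sitting exclusively on hubs), then
    shifted by ``score_shift`` so the strict above-mean filter recovers
    them with high probability.  Scores are clipped at zero.  Returns
    columns ``gene, score, pathogenic``.
    """
    rng = config.rng(_STAGE_SCORES)
    genes = sorted(network.nodes)
    scores = rng.normal(config.score_mean, config.score_sd, size=len(genes))
    module = _walk_neighbourhood(rng, network, genes, config.n_pathogenic, n_seeds=3)
    index = {g: i for i, g in enumerate(genes)}
    designated = np.array(sorted(index[g] for g in module), dtype=int)
    scores[designated] += config.score_shift
    flags = np.zeros(len(genes), dtype=bool)
    flags[designated] = True
    return pd.DataFrame({"gene": genes, "score": np.clip(scores, 0.0, None), "pathogenic": flags})


def _walk_neighbourhood(
    rng: np.random.Generator, network: nx.Graph, genes: list, size: int, n_seeds: int = 1
) -> set:
    """Grow a gene set of ``size`` by random walks from uniformly drawn seeds."""
    seeds = [genes[rng.integers(len(genes))] for _ in range(min(n_seeds, size))]
    members = set(seeds)
    current = seeds[0]
    while len(members) < min(size, len(genes)):
        nbrs = list(network.neighbors(current))
        if not nbrs:
            current = genes[rng.integers(len(genes))]
            continue
        current = nbrs[rng.integers(len(nbrs))]
        members.add(current)
        if rng.random() < 0.1:  # restart keeps the set compact around its seeds
            current = seeds[rng.integers(len(seeds))]
    return members


def _adme_draw(rng: np.random.Generator, passing: bool) -> tuple:
    """OB / Caco-2 / DL triple; ``passing`` forces all three cutoffs."""
    if passing:
        return (
            float(np.round(rng.uniform(32.0, 90.0), 2)),
            float(np.round(rng.uniform(0.0, 1.5), 2)),
            float(np.round(rng.uniform(0.20, 0.85), 2)),
        )
    return (
        float(np.round(rng.uniform(5.0, 90.0), 2)),
        float(np.round(rng.uniform(-1.5, 1.5), 2)),
        float(np.round(rng.uniform(0.01, 0.85), 2)),
    )


def generate_formula(
    config: SyntheticConfig, network: nx.Graph, scores: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Ingredient table, target map and ground truth.

    Core ingredients always pass the ADME screen and draw each target,
    with probability ``core_target_bias``, degree-weighted from the pool
    of pathogenic genes and their direct PPI neighbours; otherwise (and
    for filler ingredients always) targets are uniform over all genes.
    """
    rng = config.rng(_STAGE_FORMULA)
    pathogenic = set(scores.loc[scores["pathogenic"], "gene"])
    adjacent_pool = sorted(
        pathogenic | {nbr for g in pathogenic if g in network for nbr in network.neighbors(g)}
    )
    pool_w = np.array([network.degree(g) for g in adjacent_pool], dtype=float) + 1.0
    pool_p = pool_w / pool_w.sum() if len(adjacent_pool) else None
    genes = sorted(network.nodes)

    n_total = config.n_herbs * config.ingredients_per_herb
    core_idx = set(rng.choice(n_total, size=config.planted_core_size, replace=False).tolist())

    records, map_rows = [], []
    truth = GroundTruth(pathogenic_genes=set(pathogenic))
    for i in range(n_total):
        herb = f"Herb{i // config.ingredients_per_herb + 1:02d}"
        mol = f"SMOL{i + 1:04d}"
        is_core = i in core_idx
        ob, caco2, dl = _adme_draw(rng, passing=is_core)
        records.append((herb, mol, f"synthetic compound {i + 1}", ob, caco2, dl))
        if is_core:
            truth.core_ingredient_ids.add(mol)
        n_targets = (
            config.targets_per_core_ingredient if is_core else config.targets_per_filler_ingredient
        )
        chosen = set()
        while len(chosen) < min(n_targets, len(genes)):
            if is_core and pool_p is not None and rng.random() < config.core_target_bias:
                gene = adjacent_pool[rng.choice(len(adjacent_pool), p=pool_p)]
            else:
                gene = genes[rng.integers(len(genes))]
            chosen.add(gene)
        map_rows.extend((mol, g) for g in sorted(chosen))

    ingredients = pd.DataFrame(
        records, columns=["herb", "ingredient_id", "name", "ob", "caco2", "dl"]
    )
    target_map = pd.DataFrame(map_rows, columns=["ingredient_id", "gene"])
    return ingredients, target_map, truth


def generate_pathways(
    config: SyntheticConfig, network: nx.Graph, pathogenic=None
) -> dict:
    """Annotation terms as random-walk neighbourhoods around seed genes.

    Each term grows by walking the PPI from a seed gene, so terms are
    locally coherent gene sets — enrichment of a network-localised query
    then has real signal, unlike uniform draws.  When ``pathogenic`` is
    given, every second term is seeded inside it, emulating the
    disease-associated share of a curated pathway collection (without it,
    disease-gene enrichment would have nothing to find).
    """
    rng = config.rng(_STAGE_PATHWAYS)
    genes = sorted(network.nodes)
    disease_pool = sorted(pathogenic) if pathogenic else []
    terms = {}
    for t in range(config.n_pathways):
        if disease_pool and t % 2 == 0:
            seed_gene = disease_pool[rng.integers(len(disease_pool))]
        else:
            seed_gene = genes[rng.integers(len(genes))]
        members = {seed_gene}
        current = seed_gene
        while len(members) < min(config.pathway_size, len(genes)):
            nbrs = list(network.neighbors(current))
            if not nbrs:
                current = genes[rng.integers(len(genes))]
                continue
            current = nbrs[rng.integers(len(nbrs))]
            members.add(current)
            if rng.random() < 0.1:  # occasional restart keeps sets compact
                current = seed_gene
        terms[f"PATH{t + 1:03d}"] = members
    return terms


def generate_all(config: SyntheticConfig) -> dict:
    """Run every stage; returns ppi, scores, ingredients, target_map, pathways, truth."""
    ppi = generate_ppi(config)
    scores = generate_disease_scores(config, ppi)
    ingredients, target_map, truth = generate_formula(config, ppi, scores)
    pathways = generate_pathways(config, ppi, pathogenic=truth.pathogenic_genes)
    truth.pathway_membership = pathways
    return {
        "ppi": ppi,
        "scores": scores,
        "ingredients": ingredients,
        "target_map": target_map,
        "pathways": pathways,
        "truth": truth,
        "config": config,
    }


def write_inputs(data: dict, outdir) -> dict:
    """Write all generated inputs as plain-text files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ppi": outdir / "ppi_edges.tsv",
        "scores": outdir / "disease_scores.tsv",
        "ingredients": outdir / "ingredients.csv",
        "target_map": outdir / "target_map.tsv",
        "pathways": outdir / "pathways.gmt",
        "truth": outdir / "ground_truth.json",
        "config": outdir / "config.json",
    }
    with open(paths["ppi"], "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in data["ppi"].edges):
            fh.write(f"{a}\t{b}\n")
    data["scores"][["gene", "score"]].to_csv(paths["scores"], sep="\t", index=False)
    data["ingredients"].to_csv(paths["ingredients"], index=False)
    data["target_map"].to_csv(paths["target_map"], sep="\t", index=False)
    with open(paths["pathways"], "w") as fh:
        for term, members in sorted(data["pathways"].items()):
            fh.write("\t".join([term, f"synthetic pathway {term}"] + sorted(members)) + "\n")
    data["truth"].to_json(paths["truth"])
    Path(paths["config"]).write_text(json.dumps(asdict(data["config"]), indent=2) + "\n")
    return {k: str(v) for k, v in paths.items()}
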