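"""End-to-end orchestration of the core-ingredient-selection pipeline.

Stage order: inputs (synthetic generation or file loading) -> ADME screen
-> network assembly (disease / C-T / C-T-P) -> BD scoring of the disease
network -> potential-effect-space classification and response-protein
selection -> contribution-index ranking and FCIG cutoff -> validation
(enrichment coverage, Venn retention, functional similarity, and planted
-core recovery when ground truth exists).

Every stage writes its intermediates under the output directory, and the
machine-readable run report records only relative paths, so two runs with
the same configuration and seed produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import core, effect_space, enrichment, networks, screen, synthetic
from .importance import bd_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

REPORT_SCHEMA_VERSION = 1
_INPUT_KEYS = ("ppi", "scores", "ingredients", "target_map", "pathways")


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage}: {message}")


@dataclass
class RunConfig:
    """Validated run configuration.

    Exactly one of ``input_paths`` (the five real input files) or
    ``synthetic`` must be provided.
    """

    outdir: str = "fcig_run"
    seed: int = 0
    input_paths: dict | None = None
    synthetic: synthetic.SyntheticConfig | None = None
    whitelist_path: str | None = None
    thresholds: screen.AdmeThresholds = field(default_factory=screen.AdmeThresholds)
    ci_mode: str = "bd_sum"
    fcig_threshold: float = 0.90
    alpha: float = 0.05
    adjust_pvalues: bool = False
    ordered_pairs: bool = False
    min_confidence: float | None = None

    def __post_init__(self):
        if (self.input_paths is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_paths / synthetic must be set")
        if self.input_paths is not None:
            missing = [k for k in _INPUT_KEYS if k not in self.input_paths]
            if missing:
                raise ValueError(f"input_paths missing keys: {missing}")
            absent = [p for p in self.input_paths.values() if not Path(p).is_file()]
            if self.whitelist_path and not Path(self.whitelist_path).is_file():
                absent.append(self.whitelist_path)
            if absent:
                raise ValueError(f"input files not found: {absent}")
        if self.ci_mode not in core.CI_MODES:
            raise ValueError(f"unknown ci_mode {self.ci_mode!r}")
        if not 0.0 < self.fcig_threshold <= 1.0:
            raise ValueError("fcig_threshold must lie in (0, 1]")

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        if payload.get("synthetic") is not None:
            payload["synthetic"] = synthetic.SyntheticConfig(**payload["synthetic"])
        if payload.get("thresholds") is not None:
            payload["thresholds"] = screen.AdmeThresholds(**payload["thresholds"])
        return cls(**payload)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        payload = yaml.safe_load(text)
        if not isinstance(payload, dict):
            raise ValueError(f"{path}: expected a mapping at top level")
        return cls.from_dict(payload)

    def to_dict(self) -> dict:
        payload = dataclasses.asdict(self)
        return payload


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "seed": config.seed, "stages": {}}
    manifest: list[str] = []

    def emit(relpath: str, writer) -> None:
        writer(outdir / relpath)
        manifest.append(relpath)

    # -- stage: inputs ------------------------------------------------
    stage = "inputs"
    try:
        truth = None
        if config.synthetic is not None:
            syn_cfg = dataclasses.replace(config.synthetic, seed=config.seed)
            data = synthetic.generate_all(syn_cfg)
            written = synthetic.write_inputs(data, outdir / "inputs")
            manifest.extend(sorted(f"inputs/{Path(p).name}" for p in written.values()))
            ppi = data["ppi"]
            score_table = data["scores"][["gene", "score"]]
            ingredients = data["ingredients"]
            target_map = data["target_map"]
            pathways = data["pathways"]
            truth = data["truth"]
            whitelist = set()
        else:
            paths = config.input_paths
            ppi = networks.load_ppi(paths["ppi"], min_confidence=config.min_confidence)
            score_table = pd.read_csv(paths["scores"], sep="\t")
            ingredients = screen.read_ingredients(paths["ingredients"])
            target_map = pd.read_csv(paths["target_map"], sep="\t")
            pathways = enrichment.read_gmt(paths["pathways"])
            whitelist = (
                screen.read_whitelist(config.whitelist_path) if config.whitelist_path else set()
            )
        report["stages"]["inputs"] = {
            "mode": "synthetic" if config.synthetic is not None else "files",
            "n_ppi_nodes": ppi.number_of_nodes(),
            "n_ppi_edges": ppi.number_of_edges(),
            "n_scored_genes": int(len(score_table)),
            "n_ingredient_rows": int(len(ingredients)),
            "n_target_rows": int(len(target_map)),
            "n_pathways": len(pathways),
        }
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: screen ------------------------------------------------
    stage = "screen"
    try:
        active = screen.adme_screen(ingredients, config.thresholds, whitelist)
        shared = screen.shared_ingredients(active)
        specific = screen.specific_ingredients(active)
        emit("active_ingredients.tsv", lambda p: active.to_csv(p, sep="\t", index=False))
        emit("shared_ingredients.tsv", lambda p: shared.to_csv(p, sep="\t", index=False))
        emit("specific_ingredients.tsv", lambda p: specific.to_csv(p, sep="\t", index=False))
        report["stages"]["screen"] = {
            "n_candidates": int(len(ingredients)),
            "n_active": int(len(active)),
            "n_whitelist_only": int((active["pass_reason"] == "whitelist").sum()),
            "n_shared": int(len(shared)),
            "n_specific": int(len(specific)),
        }
        if len(active) == 0:
            raise ValueError("no ingredient survived screening")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: assemble ----------------------------------------------
    stage = "assemble"
    try:
        pathogenic = networks.filter_pathogenic(score_table)
        disease_net = networks.build_disease_network(pathogenic, ppi)
        ct = networks.build_ct_network(active, target_map)
        ctp = networks.build_ctp_network(ct, ppi, pathogenic)
        emit("disease_network.sif", lambda p: networks.write_sif(disease_net, p))
        emit("ct_network.sif", lambda p: networks.write_sif(ct, p))
        emit("ctp_network.graphml", lambda p: networks.write_graphml(ctp, p))
        report["stages"]["assemble"] = {
            "n_pathogenic": len(pathogenic),
            "mean_score": round(pathogenic.mean_score, 6),
            "disease_network": networks.network_summary(disease_net),
            "ct_network": networks.network_summary(ct),
            "ctp_network": networks.network_summary(ctp),
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: score -------------------------------------------------
    stage = "score"
    try:
        disease_bd = bd_table(disease_net, ordered_pairs=config.ordered_pairs)
        emit("disease_bd_scores.tsv", lambda p: disease_bd.to_csv(p, sep="\t", index=False))
        report["stages"]["score"] = {
            "n_scored_nodes": int(len(disease_bd)),
            "max_bd": round(float(disease_bd["bd"].max()), 6) if len(disease_bd) else None,
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: pes ---------------------------------------------------
    stage = "pes"
    try:
        target_genes = {n for n, k in ct.nodes(data="kind") if k == "gene"}
        space = effect_space.classify_pes(ctp, pathogenic.genes, target_genes)
        response = effect_space.select_response_proteins(space, ordered_pairs=config.ordered_pairs)
        cat = space.category_table()
        merged = response.bd_table.merge(
            cat.rename(columns={"gene": "node"}), on="node", how="left"
        )
        emit("pes_proteins.tsv", lambda p: merged.to_csv(p, sep="\t", index=False))
        report["stages"]["pes"] = {
            "categories": space.category_sizes(),
            "n_response_proteins": len(response.proteins),
            "bd_threshold": round(float(response.threshold), 6),
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: fcig --------------------------------------------------
    stage = "fcig"
    try:
        bd_map = dict(zip(response.bd_table["node"], response.bd_table["bd"]))
        ci = core.contribution_index(
            target_map, response.proteins, bd_map,
            ci_mode=config.ci_mode, ingredient_ids=set(active["ingredient_id"]),
        )
        fcig_result = core.cumulative_fcig(ci, threshold=config.fcig_threshold)
        named = fcig_result.merge(
            active.drop_duplicates("ingredient_id")[["ingredient_id", "name"]],
            on="ingredient_id", how="left",
        )
        emit("fcig.tsv", lambda p: named.to_csv(p, sep="\t", index=False))
        emit("cumulative_curve.csv", lambda p: named[["ingredient_id", "rate", "cum_rate"]]
             .to_csv(p, index=False))
        fcig_ids = sorted(fcig_result.loc[fcig_result["fcig"], "ingredient_id"])
        report["stages"]["fcig"] = {
            "ci_mode": config.ci_mode,
            "threshold": config.fcig_threshold,
            "n_fcig": len(fcig_ids),
            "fcig_ids": fcig_ids,
            "cum_rate_at_cutoff": round(
                float(fcig_result.loc[fcig_result["fcig"], "cum_rate"].iloc[-1]), 6
            ),
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: validate ----------------------------------------------
    stage = "validate"
    try:
        background = set().union(*pathways.values()) if pathways else set()
        enr_pathogenic = enrichment.hypergeometric_enrich(
            pathogenic.genes & background, pathways,
            alpha=config.alpha, adjust=config.adjust_pvalues,
        )
        enr_response = enrichment.hypergeometric_enrich(
            set(response.proteins) & background, pathways,
            alpha=config.alpha, adjust=config.adjust_pvalues,
        )
        coverage = enrichment.pathway_coverage(enr_response, enr_pathogenic)

        fcig_ids = set(report["stages"]["fcig"]["fcig_ids"])
        ct_genes = set(target_map["gene"]) & set(ctp.nodes)
        fcig_genes = set(target_map.loc[target_map["ingredient_id"].isin(fcig_ids), "gene"])
        venn = enrichment.venn_overlap(ct_genes, fcig_genes, pathogenic.genes)

        enr_ct = enrichment.hypergeometric_enrich(
            ct_genes & background, pathways, alpha=config.alpha, adjust=config.adjust_pvalues,
        )
        enr_fcig = enrichment.hypergeometric_enrich(
            fcig_genes & background, pathways, alpha=config.alpha, adjust=config.adjust_pvalues,
        )
        similarity = enrichment.functional_similarity(enr_fcig, enr_ct)
        emit("enrichment_response.tsv", lambda p: enr_response.to_csv(p, sep="\t", index=False))
        emit("enrichment_pathogenic.tsv", lambda p: enr_pathogenic.to_csv(p, sep="\t", index=False))
        block = {
            "n_enriched_pathogenic": int(enr_pathogenic["enriched"].sum()),
            "n_enriched_response": int(enr_response["enriched"].sum()),
            "response_coverage": None if coverage.coverage != coverage.coverage
            else round(coverage.coverage, 6),
            "venn": {k: (v if v == v else None) for k, v in venn.items()},
            "functional_similarity": round(similarity, 6),
        }
        if truth is not None:
            precision, recall = core.recover_planted_core(fcig_result, truth)
            block["planted_core"] = {
                "precision": None if precision != precision else round(precision, 6),
                "recall": None if recall != recall else round(recall, 6),
            }
        report["stages"]["validate"] = block
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    report["manifest"] = sorted(set(manifest))
    _write_json(outdir / "report.json", report)
    return report
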