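"""End-to-end orchestration: simulate -> hazard -> GWAS -> annotate -> GSEA
(-> expression QC, qPCR), with a manifest, the variant/gene accounting
summary, and a validation mode for externally deposited GWA output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as annot_mod
from . import expression_qc, gsea, io, qpcr, simulate, survival
from . import gwas as gwas_mod

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and stage toggles for one pipeline run.

    All thresholds are inclusive: the standard and relaxed association
    cutoffs (P <= 1e-5 and P <= 1e-4), the MAF filter (>= 0.05), the 1 kb
    assignment window, the GSEA reporting filter (corrected P <= 0.05,
    ES >= 0.50, n >= 5) and the minimum ortholog confidence score (5).
    """

    maf_min: float = 0.05
    p_standard: float = 1e-5
    p_relaxed: float = 1e-4
    window: int = 1000
    gsea_p_max: float = 0.05
    gsea_es_min: float = 0.50
    gsea_n_min: int = 5
    gsea_n_perm: int = 1000
    ortholog_min_score: int = 5
    phenotype_column: str = "hr"
    stages: tuple = ("simulate", "hazard", "gwas", "annotate", "gsea")
    seed: int = 0
    sim: simulate.SimulationConfig | None = None

    def __post_init__(self):
        if min(self.maf_min, self.p_standard, self.p_relaxed, self.window) <= 0:
            raise ValueError("thresholds must be positive")
        if self.p_standard > self.p_relaxed:
            raise ValueError("p_standard must be <= p_relaxed")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            cfg.sim = simulate.SimulationConfig(**sim_raw)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def threshold_counts(
    association: pd.DataFrame,
    assignments: pd.DataFrame | None = None,
    thresholds: tuple = (1e-5, 1e-4),
    orthologs: pd.DataFrame | None = None,
    ortholog_min_score: int = 5,
) -> dict:
    """Variant and gene accounting at each inclusive P threshold.

    Per threshold: variants passing, variants within 1 kb of a gene, the
    per-site-class breakdown, unique assigned genes, and (when an ortholog
    table is given) genes with a confident ortholog.
    """
    out = {}
    merged = association
    if assignments is not None:
        merged = association.merge(assignments, on="variant_id", how="left")
    for thr in thresholds:
        passing = merged[merged["p_score"] <= thr]
        entry = {"n_variants": int(len(passing))}
        if assignments is not None:
            within = passing[
                passing["gene_id"].notna() & (passing["site_class"] != "unassigned")
            ]
            entry["n_within_1kb"] = int(len(within))
            entry["site_class_counts"] = (
                within["site_class"].value_counts().sort_index().to_dict()
            )
            genes = sorted(within["gene_id"].unique())
            entry["n_unique_genes"] = len(genes)
            if orthologs is not None:
                eligible = orthologs[orthologs["score"] >= ortholog_min_score]
                entry["n_genes_with_ortholog"] = int(
                    sum(g in set(eligible["source_gene"]) for g in genes)
                )
        out[f"p<={thr:g}"] = entry
    return out


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the enabled stages in order, writing one artifact per stage plus
    a manifest (stages, seeds, output hashes, row counts) and the accounting
    summary.  A stage failure aborts with the stage named; earlier outputs
    are kept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = config.sim or simulate.SimulationConfig(seed=config.seed)
    manifest: dict = {"stages": [], "seed": config.seed, "outputs": {}}
    state: dict = {}

    def record(name: str, path: Path, n_rows: int):
        manifest["outputs"][name] = {
            "path": str(path), "sha256": _sha256(path), "n_rows": n_rows,
        }

    for stage in config.stages:
        try:
            if stage == "simulate":
                panel, truth = simulate.simulate_panel(sim_cfg)
                surv = simulate.simulate_survival(panel, truth, sim_cfg)
                annot, sets = simulate.simulate_annotation(panel, sim_cfg, truth)
                io.write_genotypes(panel, outdir / "genotypes.tsv")
                io.write_survival(surv, outdir / "survival.csv")
                io.write_annotation(annot, outdir / "annotation.tsv")
                io.write_gmt(sets, outdir / "gene_sets.gmt")
                state.update(panel=panel, truth=truth, surv=surv,
                             annot=annot, sets=sets)
                record("genotypes", outdir / "genotypes.tsv", panel.n_variants)
                record("survival", outdir / "survival.csv", len(surv))
                record("annotation", outdir / "annotation.tsv", len(annot))
                record("gene_sets", outdir / "gene_sets.gmt", len(sets))
            elif stage == "hazard":
                hr = survival.fit_all_strains(state["surv"])
                io.write_hazard(hr, outdir / "hazard.csv")
                state["hr"] = hr
                record("hazard", outdir / "hazard.csv", len(hr))
            elif stage == "gwas":
                panel = state["panel"]
                filtered, report = gwas_mod.filter_variants(panel, config.maf_min)
                K = gwas_mod.centered_grm(filtered)
                hr = state["hr"]
                y = (
                    hr.set_index("strain")
                    .loc[panel.strains, config.phenotype_column]
                    .to_numpy()
                )
                assoc = gwas_mod.lmm_association(y, filtered, K)
                io.write_association(assoc, outdir / "association.tsv")
                state.update(assoc=assoc, filter_report=report, filtered=filtered)
                record("association", outdir / "association.tsv", len(assoc))
            elif stage == "annotate":
                index = annot_mod.load_annotation(state["annot"])
                assigned = annot_mod.assign_variants(
                    state["filtered"].variants, index, config.window
                )
                assigned.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
                state["assigned"] = assigned
                record("assignments", outdir / "assignments.tsv", len(assigned))
            elif stage == "gsea":
                ranked = gsea.build_ranked_list(state["assigned"], state["assoc"])
                results = gsea.permutation_significance(
                    ranked, {k: set(v) for k, v in state["sets"].items()},
                    n_perm=config.gsea_n_perm, seed=config.seed,
                )
                results.to_csv(outdir / "gsea.tsv", sep="\t", index=False)
                state["gsea"] = results
                record("gsea", outdir / "gsea.tsv", len(results))
            elif stage == "expr-qc":
                expr = simulate.simulate_counts_and_ct(sim_cfg)
                sf, norm = expression_qc.median_of_ratios_normalize(expr.counts)
                report = expression_qc.pca_outlier_detection(norm)
                sf.to_csv(outdir / "size_factors.csv")
                report.scores.to_csv(outdir / "outlier_report.csv")
                state["expr"] = expr
                state["outliers"] = report
                record("size_factors", outdir / "size_factors.csv", len(sf))
                record("outlier_report", outdir / "outlier_report.csv",
                       len(report.scores))
            elif stage == "qpcr":
                expr = state.get("expr") or simulate.simulate_counts_and_ct(sim_cfg)
                summary, per_rep = qpcr.delta_delta_ct(expr.ct)
                summary.to_csv(outdir / "fold_changes.csv", index=False)
                state["qpcr"] = summary
                record("fold_changes", outdir / "fold_changes.csv", len(summary))
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception:
            log.error("pipeline stage %r failed", stage)
            raise
        manifest["stages"].append(stage)

    if "assoc" in state and "assigned" in state:
        manifest["summary"] = threshold_counts(
            state["assoc"], state["assigned"],
            thresholds=(config.p_standard, config.p_relaxed),
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def validate_deposited(
    gwa_output_path,
    annotation_path,
    ortholog_path=None,
    thresholds: tuple = (1e-5, 1e-4),
    window: int = 1000,
) -> dict:
    """Accounting summary for an externally deposited association output.

    Feeds a GWA association table (chr, pos, variant_id, maf, beta, se,
    p_score) and a gene annotation straight into assignment and threshold
    counting, skipping the in-package GWAS — the mode used to cross-check
    published variant/gene counts.
    """
    assoc = io.read_association(gwa_output_path)
    annot = io.read_annotation(annotation_path)
    index = annot_mod.load_annotation(annot)
    assigned = annot_mod.assign_variants(
        assoc[["variant_id", "chrom", "pos"]], index, window
    )
    orthologs = io.read_orthologs(ortholog_path) if ortholog_path else None
    return threshold_counts(assoc, assigned, thresholds, orthologs)
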