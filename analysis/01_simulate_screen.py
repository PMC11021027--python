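#!/usr/bin/env python
"""Generate the synthetic preconditioning screen used by the downstream
analysis scripts.

Writes genotypes, fly-level survival records, the gene annotation, gene
sets, an ortholog score table, an expression count matrix and a qPCR Ct
table under results/screen/.  The panel is 120 strains x 2000 variants with
8 causal variants of alternating sign, so the screen contains both strains
that benefit from preconditioning and strains harmed by it.
"""

from pathlib import Path

from precond import io
from precond.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_counts_and_ct,
    simulate_orthologs,
    simulate_panel,
    simulate_survival,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "screen"
OUT.mkdir(parents=True, exist_ok=True)

cfg = SimulationConfig(
    n_strains=120, n_variants=2000, flies_per_arm=100,
    rnaseq_outlier_shift=8.0, seed=42,
)

panel, truth = simulate_panel(cfg)
io.write_genotypes(panel, OUT / "genotypes.tsv")
print(f"panel: {panel.n_strains} strains x {panel.n_variants} variants "
      f"({(panel.variants.n_alleles != 2).sum()} non-biallelic, "
      f"{(panel.maf() < 0.05).sum()} below MAF 0.05)")

surv = simulate_survival(panel, truth, cfg)
io.write_survival(surv, OUT / "survival.csv")
print(f"survival: {len(surv)} fly records, "
      f"{surv.event.mean():.1%} deaths observed before the "
      f"{cfg.censor_horizon_h:.0f} h horizon")

annot, sets = simulate_annotation(panel, cfg, truth)
io.write_annotation(annot, OUT / "annotation.tsv")
io.write_gmt(sets, OUT / "gene_sets.gmt")
genes = annot[annot.feature == "gene"]
print(f"annotation: {len(genes)} genes; gene sets: "
      + ", ".join(f"{k} ({len(v)})" for k, v in sets.items()))

orth = simulate_orthologs(sorted(genes.gene_id), cfg)
orth.to_csv(OUT / "orthologs.tsv", sep="\t", index=False)

expr = simulate_counts_and_ct(cfg)
io.write_counts(expr.counts, OUT / "counts.tsv")
io.write_ct(expr.ct, OUT / "ct.csv")
print(f"expression: {expr.counts.shape[0]} genes x {expr.counts.shape[1]} "
      f"samples (planted outlier: {expr.outlier_sample}); "
      f"qPCR: {len(expr.ct)} Ct rows")

truth.per_strain_true_log_hr.rename("true_log_hr").to_csv(
    OUT / "true_log_hr.csv"
)
with open(OUT / "causal_variants.txt", "w") as fh:
    fh.write("\n".join(truth.causal_variant_ids) + "\n")
print(f"ground truth: causal variants {truth.causal_variant_ids}")
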