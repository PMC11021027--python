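#!/usr/bin/env python
"""Variant-to-gene assignment, candidate-gene ranking, ortholog lookup and
gene-set enrichment on the GWAS output.

Mirrors the screen's accounting: variants passing the standard (P <= 1e-5)
and relaxed (P <= 1e-4) thresholds, how many lie within 1 kb of a gene and
in which site class, the unique candidate genes ranked by their best
variant, orthologs at confidence >= 5, and the permutation-based enrichment
of the planted gene set."""

from pathlib import Path

import pandas as pd

from precond import io
from precond.annotation import (
    assign_variants,
    attach_orthologs,
    load_annotation,
    rank_genes,
)
from precond.gsea import build_ranked_list, filter_terms, permutation_significance
from precond.pipeline import threshold_counts

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCREEN = RESULTS / "screen"

assoc = io.read_association(RESULTS / "association.tsv")
annot = io.read_annotation(SCREEN / "annotation.tsv")
index = load_annotation(annot)

assigned = assign_variants(assoc[["variant_id", "chrom", "pos"]], index)
assigned.to_csv(RESULTS / "assignments.tsv", sep="\t", index=False)
print("site classes over all tested variants:",
      assigned.site_class.value_counts().to_dict())

counts = threshold_counts(assoc, assigned, thresholds=(1e-5, 1e-4))
for key, entry in counts.items():
    print(f"{key}: {entry['n_variants']} variants, "
          f"{entry['n_within_1kb']} within 1 kb of a gene "
          f"({entry['site_class_counts']}), "
          f"{entry['n_unique_genes']} unique genes")

genes = rank_genes(assigned, assoc, p_threshold=1e-4)
orth = io.read_orthologs(SCREEN / "orthologs.tsv")
genes = attach_orthologs(genes, orth)
genes.to_csv(RESULTS / "candidate_genes.tsv", sep="\t", index=False)
n_orth = genes["ortholog"].notna().sum()
print(f"candidate genes at P<=1e-4: {len(genes)}; "
      f"{n_orth} have an ortholog at score >= 5")
print(genes.head(5).to_string(index=False))

sets = {k: set(v) for k, v in io.read_gmt(SCREEN / "gene_sets.gmt").items()}
ranked = build_ranked_list(assigned, assoc)
res = permutation_significance(ranked, sets, n_perm=1000, seed=42)
res.to_csv(RESULTS / "gsea.tsv", sep="\t", index=False)
print("\nenrichment results:")
print(res.drop(columns="leading_edge").to_string(index=False))
kept = filter_terms(res)
print(f"sets passing the reporting filter "
      f"(corrected P<=0.05, ES>=0.50, n>=5): {list(kept['set'])}")
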