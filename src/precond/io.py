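"""Plain-text readers and writers for the pipeline's file formats.

Genotypes: TSV with columns variant_id, chrom, pos, ref, alt, n_alleles and
one column per strain holding 0/1 dosages (NA = missing).  Annotation: TSV
with gene_id, chrom, feature (gene|exon|UTR|intron), start, end — 1-based
inclusive.  Gene sets: standard GMT.  Survival: CSV with strain, arm,
time_h, event.  Association, hazard, counts and Ct tables are
self-describing CSV/TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .gwas import GenotypePanel

_META_COLS = ["variant_id", "chrom", "pos", "ref", "alt", "n_alleles"]


def write_genotypes(panel: GenotypePanel, path) -> None:
    meta = panel.variants[_META_COLS].copy()
    dose = pd.DataFrame(
        panel.dosage.T, columns=panel.strains, index=meta.index
    )
    out = pd.concat([meta, dose], axis=1)
    out.to_csv(path, sep="\t", index=False, float_format="%.0f", na_rep="NA")


def read_genotypes(path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    strains = [c for c in df.columns if c not in _META_COLS]
    dosage = df[strains].to_numpy(dtype=float).T
    variants = df[_META_COLS].reset_index(drop=True)
    return GenotypePanel(strains=strains, variants=variants, dosage=dosage)


def write_survival(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.1f")


def read_survival(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_annotation(annot: pd.DataFrame, path) -> None:
    annot.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gmt(gene_sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(gene_sets[name])
            fh.write(f"{name}\tsynthetic\t{genes}\n")


def read_gmt(path) -> dict:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_association(assoc: pd.DataFrame, path) -> None:
    # column order aligned with deposited GWA-output conventions
    out = assoc.rename(columns={"chrom": "chr"})[
        ["chr", "pos", "variant_id", "maf", "beta", "se", "p_score"]
    ]
    out.to_csv(path, sep="\t", index=False)


def read_association(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.rename(columns={"chr": "chrom"})


def write_hazard(hr_table: pd.DataFrame, path) -> None:
    hr_table.to_csv(path, index=False)


def read_hazard(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_ct(ct: pd.DataFrame, path) -> None:
    ct.to_csv(path, index=False)


def read_ct(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_orthologs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"source_gene", "target_gene", "score"}
    if missing := required - set(df.columns):
        raise ValueError(f"ortholog table missing columns {sorted(missing)}")
    return df
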