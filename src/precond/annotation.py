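"""Variant-to-gene assignment with feature-class priority, gene ranking,
and ortholog attachment.

A variant is assigned to the single gene, among all genes whose interval
(plus a +/- 1 kb flank) contains it, with the highest site-class priority:
exon > UTR > intron > flanking (upstream and downstream share the lowest
tier).  Within the winning class, ties go to the smaller variant-to-gene
distance, then to the lexicographically smaller gene id.  Coordinates are
1-based inclusive and strand is ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 1000

#: smaller = higher priority; upstream/downstream share one tier
SITE_PRIORITY = {"exon": 0, "UTR": 1, "intron": 2, "upstream": 3, "downstream": 3}


@dataclass
class GeneModel:
    """One gene interval with typed sub-intervals (exon / UTR / intron)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    features: list = field(default_factory=list)  # (feature, start, end)

    def site_class_at(self, pos: int) -> str:
        """Feature class of a position inside the gene interval.

        Exon wins over UTR if sub-intervals overlap; positions covered by no
        sub-interval are intronic (gene bodies are exhaustively genic).
        """
        classes = {f for f, s, e in self.features if s <= pos <= e}
        for cls in ("exon", "UTR", "intron"):
            if cls in classes:
                return cls
        return "intron"


@dataclass
class GeneAssignment:
    variant_id: str
    gene_id: str | None
    site_class: str  # exon|UTR|intron|upstream|downstream|unassigned
    distance: int    # bp to the gene interval; 0 if inside


class AnnotationIndex:
    """Per-chromosome interval index over gene bodies."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = {g.gene_id: g for g in genes}
        if len(self.genes) != len(genes):
            raise ValueError("duplicate gene ids in annotation")
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            # half-open tree coordinates over the 1-based inclusive interval
            self._trees.setdefault(g.chrom, IntervalTree()).addi(
                g.start, g.end + 1, g.gene_id
            )

    def candidates(self, chrom: str, pos: int, window: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(pos - window, pos + window + 1)
        return [self.genes[iv.data] for iv in hits]


def load_annotation(table: pd.DataFrame) -> AnnotationIndex:
    """Build the index from a tidy annotation table.

    Expected columns: gene_id, chrom, feature (gene|exon|UTR|intron),
    start, end — 1-based inclusive.  Every gene needs exactly one
    feature == "gene" row; sub-intervals must nest inside it.
    """
    required = {"gene_id", "chrom", "feature", "start", "end"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"annotation table missing columns {sorted(missing)}")
    if (table["start"] > table["end"]).any():
        bad = table[table["start"] > table["end"]].iloc[0]
        raise ValueError(f"malformed interval for gene {bad['gene_id']}")
    genes = []
    for gene_id, grp in table.groupby("gene_id", sort=True):
        body = grp[grp["feature"] == "gene"]
        if len(body) != 1:
            raise ValueError(f"gene {gene_id} needs exactly one 'gene' row")
        start = int(body["start"].iloc[0])
        end = int(body["end"].iloc[0])
        chrom = str(body["chrom"].iloc[0])
        feats = []
        for _, row in grp[grp["feature"] != "gene"].iterrows():
            if row["start"] < start or row["end"] > end:
                raise ValueError(
                    f"sub-interval outside gene body for {gene_id}"
                )
            feats.append((row["feature"], int(row["start"]), int(row["end"])))
        genes.append(GeneModel(gene_id, chrom, start, end, feats))
    return AnnotationIndex(genes)


def assign_variant(
    variant_id: str,
    chrom: str,
    pos: int,
    index: AnnotationIndex,
    window: int = DEFAULT_WINDOW,
) -> GeneAssignment:
    """Assign one variant to at most one gene by site-class priority."""
    best = None  # (priority, distance, gene_id, site_class)
    for gene in index.candidates(chrom, pos, window):
        if gene.start <= pos <= gene.end:
            cls = gene.site_class_at(pos)
            dist = 0
        elif pos < gene.start:
            cls = "upstream"
            dist = gene.start - pos
        else:
            cls = "downstream"
            dist = pos - gene.end
        if dist > window:
            continue
        key = (SITE_PRIORITY[cls], dist, gene.gene_id, cls)
        if best is None or key < best:
            best = key
    if best is None:
        return GeneAssignment(variant_id, None, "unassigned", -1)
    return GeneAssignment(variant_id, best[2], best[3], best[1])


def assign_variants(
    variants: pd.DataFrame, index: AnnotationIndex, window: int = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Assign every row of a variant table (variant_id, chrom, pos)."""
    rows = [
        assign_variant(v.variant_id, v.chrom, int(v.pos), index, window)
        for v in variants.itertuples()
    ]
    return pd.DataFrame(
        {
            "variant_id": [a.variant_id for a in rows],
            "gene_id": [a.gene_id for a in rows],
            "site_class": [a.site_class for a in rows],
            "distance": [a.distance for a in rows],
        }
    )


def rank_genes(
    assignments: pd.DataFrame,
    association: pd.DataFrame,
    p_threshold: float = 1e-4,
) -> pd.DataFrame:
    """Candidate-gene table ranked by each gene's most significant variant.

    Variants with p_score <= p_threshold (inclusive) and an assigned gene are
    grouped by gene; each gene scores its minimum variant P.  Sorted
    ascending by that P with gene-id tie-break.
    """
    merged = assignments.merge(association, on="variant_id", how="inner")
    if merged.empty:
        log.info("rank_genes: no shared variants between assignments and association")
        return pd.DataFrame(
            columns=["gene_id", "best_p", "n_variants", "site_classes"]
        )
    hits = merged[(merged["p_score"] <= p_threshold) & merged["gene_id"].notna()]
    rows = []
    for gene_id, grp in hits.groupby("gene_id"):
        rows.append(
            {
                "gene_id": gene_id,
                "best_p": float(grp["p_score"].min()),
                "n_variants": len(grp),
                "site_classes": ",".join(
                    f"{c}:{n}" for c, n in grp["site_class"].value_counts().sort_index().items()
                ),
            }
        )
    out = pd.DataFrame(rows, columns=["gene_id", "best_p", "n_variants", "site_classes"])
    return out.sort_values(["best_p", "gene_id"], kind="mergesort").reset_index(drop=True)


def attach_orthologs(
    gene_table: pd.DataFrame,
    orthologs: pd.DataFrame,
    min_score: int = 5,
) -> pd.DataFrame:
    """Attach the best-scoring ortholog (confidence >= min_score) per gene.

    ``orthologs`` columns: source_gene, target_gene, score.  Score ties are
    broken by lexicographic target id with a warning.
    """
    if (orthologs["score"] < 0).any():
        raise ValueError("ortholog scores must be >= 0")
    eligible = orthologs[orthologs["score"] >= min_score]
    best: dict[str, tuple] = {}
    for row in eligible.sort_values(["source_gene", "score", "target_gene"],
                                    ascending=[True, False, True]).itertuples():
        if row.source_gene not in best:
            best[row.source_gene] = (row.target_gene, row.score)
        elif best[row.source_gene][1] == row.score:
            log.warning(
                "ortholog tie for %s at score %s; keeping %s",
                row.source_gene, row.score, best[row.source_gene][0],
            )
    out = gene_table.copy()
    out["ortholog"] = [
        best.get(g, (None, None))[0] for g in out["gene_id"]
    ]
    out["ortholog_score"] = [
        best.get(g, (None, np.nan))[1] for g in out["gene_id"]
    ]
    return out
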