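#!/usr/bin/env python
"""Normalization and PCA outlier screening of the expression count matrix.

Computes median-of-ratios size factors, projects log2 normalized counts
onto PC1/PC2, applies the mean + 2 SD rule on PC1, PC2 and centroid
distance, and — as the screen's analysis did after removing its outlier
strain — renormalizes the surviving samples."""

from pathlib import Path

from precond import io
from precond.expression_qc import (
    median_of_ratios_normalize,
    pca_outlier_detection,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCREEN = RESULTS / "screen"

counts = io.read_counts(SCREEN / "counts.tsv")
sf, norm = median_of_ratios_normalize(counts)
sf.to_csv(RESULTS / "size_factors.csv")
print("size factors:",
      ", ".join(f"{s}={v:.2f}" for s, v in sf.items()))

report = pca_outlier_detection(norm)
report.scores.to_csv(RESULTS / "outlier_report.csv")
print(f"thresholds: " + ", ".join(f"{k}={v:.1f}"
      for k, v in report.thresholds.items()))
print(f"flagged outliers: {report.flagged or 'none'}")

if report.flagged:
    kept = counts.drop(columns=report.flagged)
    sf2, _ = median_of_ratios_normalize(kept)
    sf2.to_csv(RESULTS / "size_factors_after_exclusion.csv")
    print(f"renormalized {kept.shape[1]} samples after single-pass exclusion")
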