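"""Count normalization and PCA-based outlier exclusion for expression samples.

Normalization is the median-of-ratios size factor (each sample's median,
over genes expressed in every sample, of its count divided by the gene's
geometric mean across samples).  Outlier detection projects log2(x+1)
normalized counts onto the first two principal components and flags any
sample whose |PC1| or |PC2| deviation from the sample mean, or whose
distance from the PC1–PC2 centroid, exceeds the across-sample
mean + 2*SD threshold for that criterion.  Exclusion is single-pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class OutlierReport:
    scores: pd.DataFrame       # per-sample pc1, pc2, dist and per-criterion flags
    thresholds: dict           # criterion -> threshold value
    flagged: list              # sample ids exceeding >= 1 criterion


def median_of_ratios_normalize(
    counts: pd.DataFrame,
) -> tuple[pd.Series, pd.DataFrame]:
    """Size factors and normalized matrix for a genes x samples count table.

    Only genes with a nonzero count in every sample enter the median; an
    input with no such gene is rejected.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    X = counts.to_numpy(dtype=float)
    all_nonzero = (X > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no gene has nonzero counts in every sample")
    logX = np.log(X[all_nonzero])
    log_geomean = logX.mean(axis=1, keepdims=True)
    size_factors = np.exp(np.median(logX - log_geomean, axis=0))
    sf = pd.Series(size_factors, index=counts.columns, name="size_factor")
    normalized = counts / sf
    return sf, normalized


def pca_outlier_detection(normalized: pd.DataFrame) -> OutlierReport:
    """Flag expression samples by the mean + 2*SD rule on PC1, PC2 and
    centroid distance.

    The normalized genes x samples matrix is log2(x+1)-transformed, samples
    are projected onto the first two PCs, and each of the three per-sample
    statistics (|PC1 - mean|, |PC2 - mean|, Euclidean distance from the
    PC1–PC2 centroid) is compared against its own across-sample
    mean + 2*SD.  Absolute deviations make the rule invariant to the sign
    ambiguity of principal components.  A criterion with zero variance
    flags nothing.
    """
    n_samples = normalized.shape[1]
    if n_samples < 4:
        raise ValueError("need >= 4 samples for PCA outlier detection")
    X = np.log2(normalized.to_numpy(dtype=float).T + 1.0)  # samples x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U * S
    pc1 = scores[:, 0]
    pc2 = scores[:, 1] if scores.shape[1] > 1 else np.zeros(n_samples)
    # SDs below floating fuzz (relative to the matrix scale) count as zero
    eps = 1e-12 * max(1.0, float(np.linalg.norm(X)))

    def _flag_abs(v: np.ndarray):
        dev = np.abs(v - v.mean())
        sd = v.std(ddof=1)
        thr = 2.0 * sd
        return dev, thr, (dev > thr) if sd > eps else np.zeros(v.size, dtype=bool)

    dev1, thr1, f1 = _flag_abs(pc1)
    dev2, thr2, f2 = _flag_abs(pc2)
    dist = np.hypot(pc1 - pc1.mean(), pc2 - pc2.mean())
    sd_d = dist.std(ddof=1)
    thr_d = dist.mean() + 2.0 * sd_d
    fd = (dist > thr_d) if sd_d > eps else np.zeros(n_samples, dtype=bool)

    flags = f1 | f2 | fd
    report = pd.DataFrame(
        {
            "pc1": pc1,
            "pc2": pc2,
            "abs_dev_pc1": dev1,
            "abs_dev_pc2": dev2,
            "center_distance": dist,
            "flag_pc1": f1,
            "flag_pc2": f2,
            "flag_distance": fd,
            "outlier": flags,
        },
        index=normalized.columns,
    )
    return OutlierReport(
        scores=report,
        thresholds={"pc1": thr1, "pc2": thr2, "distance": thr_d},
        flagged=list(normalized.columns[flags]),
    )
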