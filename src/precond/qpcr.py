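"""Relative qPCR quantification by the delta-delta-Ct method.

Target-gene Ct values are normalized to a housekeeping gene within each
sample (dCt = Ct_target - Ct_housekeeping), then to the mean dCt of the
baseline timepoint within each genotype (ddCt); the fold change is
efficiency^(-ddCt) with the amplification efficiency fixed at 2 by default.
The aggregate fold at a timepoint is computed on the exponent scale,
efficiency^(-mean ddCt), so the baseline mean fold is exactly 1 by
construction; per-replicate linear folds carry the SEM and the paired
between-genotype t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_HOUSEKEEPING = "RpL19"
DEFAULT_BASELINE = "no_treatment"


@dataclass
class PairedTestResult:
    t: float
    p: float
    df: int
    degenerate: bool = False


def delta_delta_ct(
    table: pd.DataFrame,
    housekeeping: str = DEFAULT_HOUSEKEEPING,
    baseline: str = DEFAULT_BASELINE,
    efficiency: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fold changes relative to housekeeping gene and baseline timepoint.

    ``table`` columns: sample, genotype, timepoint, gene, ct, replicate.
    Returns (summary, per_replicate): the summary has one row per
    (genotype, timepoint, gene) with mean fold (exponent-scale mean) and the
    SEM of the per-replicate linear folds; per_replicate holds each
    replicate's ddCt and fold.
    """
    required = {"sample", "genotype", "timepoint", "gene", "ct", "replicate"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")

    hk = table[table["gene"] == housekeeping].set_index(
        ["genotype", "timepoint", "replicate"]
    )["ct"]
    targets = table[table["gene"] != housekeeping].copy()
    keys = list(zip(targets["genotype"], targets["timepoint"], targets["replicate"]))
    hk_ct = []
    for key, sample in zip(keys, targets["sample"]):
        if key not in hk.index:
            raise ValueError(
                f"no housekeeping ({housekeeping}) measurement for sample {sample!r}"
            )
        hk_ct.append(float(hk.loc[key]))
    targets["dct"] = targets["ct"].to_numpy() - np.asarray(hk_ct)

    base = targets[targets["timepoint"] == baseline]
    base_mean = base.groupby(["genotype", "gene"])["dct"].mean()
    for genotype in targets["genotype"].unique():
        for gene in targets["gene"].unique():
            if (genotype, gene) not in base_mean.index:
                raise ValueError(
                    f"no baseline ({baseline}) measurement for genotype "
                    f"{genotype!r}, gene {gene!r}"
                )
    targets["ddct"] = targets["dct"].to_numpy() - base_mean.loc[
        list(zip(targets["genotype"], targets["gene"]))
    ].to_numpy()
    targets["fold"] = efficiency ** (-targets["ddct"])

    rows = []
    for (genotype, timepoint, gene), grp in targets.groupby(
        ["genotype", "timepoint", "gene"], sort=True
    ):
        folds = grp["fold"].to_numpy()
        rows.append(
            {
                "genotype": genotype,
                "timepoint": timepoint,
                "gene": gene,
                "fold_mean": float(efficiency ** (-grp["ddct"].mean())),
                "fold_sem": float(stats.sem(folds)) if folds.size > 1 else 0.0,
                "n_replicates": folds.size,
            }
        )
    summary = pd.DataFrame(rows)
    per_rep = targets[
        ["sample", "genotype", "timepoint", "gene", "replicate", "dct", "ddct", "fold"]
    ].reset_index(drop=True)
    return summary, per_rep


def timepoint_test(
    per_replicate: pd.DataFrame,
    gene: str,
    timepoint: str,
    genotypes: tuple = ("control", "knockdown"),
    log_scale: bool = False,
) -> PairedTestResult:
    """Paired two-sided t-test of fold changes between genotypes at one
    timepoint, pairing replicates by their collection-batch index.

    Zero-variance differences are flagged degenerate instead of returning
    NaN: identical vectors give (t=0, p=1); a constant nonzero difference
    gives (t=+/-inf, p=0).
    """
    sub = per_replicate[
        (per_replicate["gene"] == gene) & (per_replicate["timepoint"] == timepoint)
    ]
    a = sub[sub["genotype"] == genotypes[0]].sort_values("replicate")["fold"].to_numpy()
    b = sub[sub["genotype"] == genotypes[1]].sort_values("replicate")["fold"].to_numpy()
    if a.size != b.size:
        raise ValueError(
            f"unequal replicate counts ({a.size} vs {b.size}) at {timepoint!r}"
        )
    if a.size < 2:
        raise ValueError("need >= 2 replicate pairs")
    if log_scale:
        a, b = np.log2(a), np.log2(b)
    d = a - b
    df = d.size - 1
    if d.std(ddof=1) == 0:
        if np.allclose(d, 0):
            return PairedTestResult(t=0.0, p=1.0, df=df, degenerate=True)
        sign = float(np.sign(d.mean()))
        return PairedTestResult(t=sign * np.inf, p=0.0, df=df, degenerate=True)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
    p = 2.0 * stats.t.sf(abs(t), df)
    return PairedTestResult(t=float(t), p=float(min(1.0, p)), df=df)
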