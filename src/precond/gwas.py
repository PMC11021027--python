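"""Linear mixed-model association of per-strain hazard ratios with genotype.

The model is the standard kinship LMM for inbred panels,

    y = alpha + x * beta + u + eps,
    u   ~ MVN_n(0, lambda * tau^-1 * K),
    eps ~ MVN_n(0, tau^-1 * I_n),

where y holds one phenotype value per strain (here a hazard ratio), x is a
variant's dosage vector, K the centered marker-based relatedness matrix and
lambda the ratio of the two variance components.  lambda is estimated once
by REML under the no-variant null and then held fixed for a per-variant
score test — the "P_score" convention of GEMMA-style software.

Everything is done in K's eigenbasis: after rotating by the eigenvectors the
covariance is diagonal with entries tau^-1 * (lambda * delta_i + 1), so each
candidate lambda costs O(n) and the per-variant score test is a whitened
simple regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)

LAMBDA_GRID_BOUNDS = (1e-5, 1e5)
LAMBDA_GRID_POINTS = 100


@dataclass
class GenotypePanel:
    """Strains x variants biallelic dosage matrix with per-variant metadata.

    Inbred lines are homozygous, so dosage is 0 (major) or 1 (minor allele);
    missing calls are NaN.  ``variants`` carries one row per column of
    ``dosage`` with at least variant_id, chrom, pos, ref, alt, n_alleles.
    """

    strains: list
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self):
        if self.dosage.shape != (len(self.strains), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.strains)} strains x {len(self.variants)} variants"
            )

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per variant over non-missing calls."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosage, axis=0)
        return np.minimum(p, 1.0 - p)

    def imputed_dosage(self) -> np.ndarray:
        """Dosage with missing calls replaced by the variant mean."""
        X = self.dosage.astype(float).copy()
        if np.isnan(X).any():
            col_mean = np.nanmean(X, axis=0)
            idx = np.where(np.isnan(X))
            X[idx] = col_mean[idx[1]]
        return X

    def subset(self, keep: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            strains=list(self.strains),
            variants=self.variants.iloc[keep].reset_index(drop=True),
            dosage=self.dosage[:, keep],
        )


@dataclass
class KinshipMatrix:
    """Centered GRM with its cached eigendecomposition."""

    K: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray


@dataclass
class NullLMM:
    """REML fit of the no-variant model y = alpha + u + eps."""

    lambda_: float
    vc_residual: float  # tau^-1, the residual variance
    alpha: float
    reml_loglik: float
    n: int


def filter_variants(
    panel: GenotypePanel, maf_min: float = 0.05
) -> tuple[GenotypePanel, dict]:
    """Keep biallelic variants with MAF >= maf_min (boundary inclusive).

    Returns the filtered panel and a removal report keyed by criterion.
    """
    maf = panel.maf()
    biallelic = panel.variants["n_alleles"].to_numpy() == 2
    maf_ok = maf >= maf_min
    keep = biallelic & maf_ok
    report = {
        "n_input": panel.n_variants,
        "removed_nonbiallelic": int((~biallelic).sum()),
        "removed_low_maf": int((biallelic & ~maf_ok).sum()),
        "n_retained": int(keep.sum()),
    }
    log.info("variant filter: %s", report)
    out = panel.subset(np.where(keep)[0])
    out.variants = out.variants.assign(maf=maf[keep])
    return out, report


def centered_grm(panel: GenotypePanel) -> KinshipMatrix:
    """Centered genetic relatedness matrix K = W W^T / p.

    W is the column-centered (mean-imputed) dosage matrix over the p
    variants.  Centering makes K annihilate constants: K . 1 = 0.
    """
    if panel.n_strains < 2:
        raise ValueError("need >= 2 strains")
    if panel.n_variants < 1:
        raise ValueError("no variants left to build the GRM from")
    W = panel.imputed_dosage()
    W = W - W.mean(axis=0, keepdims=True)
    K = (W @ W.T) / panel.n_variants
    vals, vecs = np.linalg.eigh(K)
    return KinshipMatrix(K=K, eigenvalues=vals, eigenvectors=vecs)


def _reml_loglik(log_lambda: float, delta: np.ndarray, yt: np.ndarray,
                 ot: np.ndarray) -> float:
    """Restricted log likelihood at lambda (intercept-only fixed effects),
    profiled over the residual variance; full constants kept so it matches a
    dense multivariate-normal evaluation."""
    lam = np.exp(log_lambda)
    v = lam * delta + 1.0
    if (v <= 0).any():
        return -np.inf
    w = 1.0 / v
    xwx = float(np.sum(w * ot * ot))
    alpha = float(np.sum(w * ot * yt)) / xwx
    r = yt - alpha * ot
    rss = float(np.sum(w * r * r))
    n = yt.size
    df = n - 1
    sigma2 = rss / df
    return -0.5 * (
        df * np.log(2.0 * np.pi * sigma2)
        + float(np.sum(np.log(v)))
        + np.log(xwx)
        + df
    )


def fit_null_lmm(y: np.ndarray, K: KinshipMatrix) -> NullLMM:
    """REML estimate of lambda under the null model (intercept only).

    lambda is scanned on a 100-point log grid over [1e-5, 1e5] and refined
    by bounded scalar optimization (tolerance 1e-6 in log lambda); the
    residual variance and intercept are then profiled analytically.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype vector contains non-finite values")
    n = y.size
    delta = np.maximum(K.eigenvalues, 0.0)
    U = K.eigenvectors
    yt = U.T @ y
    ot = U.T @ np.ones(n)

    lo, hi = np.log(LAMBDA_GRID_BOUNDS[0]), np.log(LAMBDA_GRID_BOUNDS[1])
    grid = np.linspace(lo, hi, LAMBDA_GRID_POINTS)
    lls = np.array([_reml_loglik(g, delta, yt, ot) for g in grid])
    i = int(np.argmax(lls))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid.size - 1)]
    if a < b:
        res = optimize.minimize_scalar(
            lambda g: -_reml_loglik(g, delta, yt, ot),
            bounds=(a, b),
            method="bounded",
            options={"xatol": 1e-6},
        )
        log_lam = float(res.x)
        # a flat likelihood (e.g. K = 0) keeps the boundary grid point
        if _reml_loglik(log_lam, delta, yt, ot) <= lls[i] + 1e-10:
            log_lam = float(grid[i])
    else:
        log_lam = float(grid[i])

    lam = float(np.exp(log_lam))
    w = 1.0 / (lam * delta + 1.0)
    xwx = float(np.sum(w * ot * ot))
    alpha = float(np.sum(w * ot * yt)) / xwx
    r = yt - alpha * ot
    vc_residual = float(np.sum(w * r * r)) / (n - 1)
    return NullLMM(
        lambda_=lam,
        vc_residual=vc_residual,
        alpha=alpha,
        reml_loglik=_reml_loglik(log_lam, delta, yt, ot),
        n=n,
    )


def lmm_association(
    y: np.ndarray,
    panel: GenotypePanel,
    K: KinshipMatrix,
    null: NullLMM | None = None,
) -> pd.DataFrame:
    """Single-variant score tests with lambda fixed at its null estimate.

    After rotating into K's eigenbasis and whitening by the per-coordinate
    standard deviations, the model is an ordinary regression; the score
    statistic for beta = 0 uses the null (intercept-only) residuals and the
    ML null variance, and is referred to chi-square with 1 df.  Monomorphic
    variants are skipped (NaN) with a log entry.

    Returns a frame with variant_id, chrom, pos, maf, beta, se, p_score.
    """
    y = np.asarray(y, dtype=float)
    if null is None:
        null = fit_null_lmm(y, K)
    n = y.size
    delta = np.maximum(K.eigenvalues, 0.0)
    U = K.eigenvectors
    sw = 1.0 / np.sqrt(null.lambda_ * delta + 1.0)

    yt = sw * (U.T @ y)
    ot = sw * (U.T @ np.ones(n))
    X = panel.imputed_dosage()
    Xt = sw[:, None] * (U.T @ X)

    oo = float(ot @ ot)
    ry = yt - ot * (float(ot @ yt) / oo)
    Rx = Xt - np.outer(ot, (ot @ Xt) / oo)

    s = ry @ Rx                      # score per variant
    xx = np.einsum("ij,ij->j", Rx, Rx)
    sigma2_0 = float(ry @ ry) / n    # ML null variance

    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(xx > 1e-12, s * s / (sigma2_0 * xx), np.nan)
        beta = np.where(xx > 1e-12, s / xx, np.nan)
        rss_full = float(ry @ ry) - np.where(xx > 1e-12, s * s / xx, 0.0)
        se = np.sqrt(np.maximum(rss_full, 0.0) / max(n - 2, 1) / np.where(xx > 1e-12, xx, np.nan))
    n_skipped = int(np.sum(~(xx > 1e-12)))
    if n_skipped:
        log.info("lmm_association: skipped %d monomorphic variants", n_skipped)
    p_score = stats.chi2.sf(T, df=1)
    p_score = np.where(np.isfinite(T), np.clip(p_score, np.nextafter(0, 1), 1.0), np.nan)

    maf = (
        panel.variants["maf"].to_numpy()
        if "maf" in panel.variants.columns
        else panel.maf()
    )
    return pd.DataFrame(
        {
            "variant_id": panel.variants["variant_id"].to_numpy(),
            "chrom": panel.variants["chrom"].to_numpy(),
            "pos": panel.variants["pos"].to_numpy(),
            "maf": maf,
            "beta": beta,
            "se": se,
            "p_score": p_score,
        }
    )


def qq_summary(pvalues) -> dict:
    """Observed vs expected -log10 quantiles and the genomic inflation factor.

    lambda_GC = median(chi2_1 quantile of observed P) / median of chi2_1.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 10:
        raise ValueError("need >= 10 P-values for a qq summary")
    obs = np.sort(p)
    expected = (np.arange(1, p.size + 1) - 0.5) / p.size
    chi2_obs = stats.chi2.isf(obs, df=1)
    lambda_gc = float(np.median(chi2_obs) / stats.chi2.ppf(0.5, df=1))
    return {
        "expected_neglog10": -np.log10(expected),
        "observed_neglog10": -np.log10(np.maximum(obs, 1e-300)),
        "lambda_gc": lambda_gc,
    }
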