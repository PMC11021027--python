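"""Per-strain Cox proportional-hazards phenotyping for two-arm survival screens.

Each strain of the screen contributes two arms (preconditioned vs control,
or knockdown vs control); the phenotype carried into association mapping is
the arm hazard ratio HR = exp(beta) from a Cox model with the arm indicator
as its single covariate.  HR < 1 means the preconditioned arm died more
slowly under the second stress.

Event times sit on a coarse monitoring grid, so ties are heavy; the partial
likelihood uses the Efron tie correction by default (Breslow available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

TREATED_ARMS = ("preconditioned", "knockdown")
CONTROL_ARM = "control"

#: |beta| beyond which the Newton iteration is declared divergent
_BETA_DIVERGENCE = 15.0
_MAX_ITER = 50
_TOL = 1e-8


@dataclass
class HazardEstimate:
    """Arm hazard ratio for one strain with Wald inference."""

    strain: str
    log_hr: float
    hr: float
    se_log_hr: float
    wald_p: float
    n_events_treated: int
    n_events_control: int
    converged: bool = True
    n_iter: int = 0

    @property
    def direction(self) -> str:
        """'beneficial' if the treated arm died more slowly, else 'detrimental'."""
        if self.hr < 1.0:
            return "beneficial"
        if self.hr > 1.0:
            return "detrimental"
        return "neutral"


def _partial_likelihood_stats(beta: float, time, event, z, ties: str):
    """Log partial likelihood, gradient and observed information for a
    single covariate Cox model at ``beta``.

    Efron's correction deflates the risk-set sums by the within-tie average
    of the tied deaths' weights; Breslow leaves the risk set whole for every
    tied death.
    """
    w = np.exp(beta * z)
    wz = w * z
    wzz = w * z * z

    loglik = 0.0
    grad = 0.0
    info = 0.0
    event_times = np.unique(time[event == 1])
    for td in event_times:
        at_risk = time >= td
        dead = (time == td) & (event == 1)
        d = int(dead.sum())
        s1 = float(z[dead].sum())
        S0, S1, S2 = w[at_risk].sum(), wz[at_risk].sum(), wzz[at_risk].sum()
        S0d, S1d, S2d = w[dead].sum(), wz[dead].sum(), wzz[dead].sum()
        if ties == "efron":
            frac = np.arange(d) / d
        else:  # breslow
            frac = np.zeros(d)
        den = S0 - frac * S0d
        num1 = S1 - frac * S1d
        num2 = S2 - frac * S2d
        loglik += beta * s1 - np.log(den).sum()
        r1 = num1 / den
        grad += s1 - r1.sum()
        info += (num2 / den - r1 * r1).sum()
    return loglik, grad, info


def _fit_cox_binary(time, event, z, ties: str = "efron"):
    """Newton–Raphson with step-halving on the single-covariate partial
    likelihood.  Returns (beta, se, converged, n_iter)."""
    beta = 0.0
    loglik, grad, info = _partial_likelihood_stats(beta, time, event, z, ties)
    n_iter = 0
    for n_iter in range(1, _MAX_ITER + 1):
        if info <= 0:
            break
        step = grad / info
        new_beta = beta + step
        new_ll, new_grad, new_info = _partial_likelihood_stats(
            new_beta, time, event, z, ties
        )
        halvings = 0
        while new_ll < loglik and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _partial_likelihood_stats(
                new_beta, time, event, z, ties
            )
            halvings += 1
        delta = new_beta - beta
        beta, loglik, grad, info = new_beta, new_ll, new_grad, new_info
        if abs(beta) > _BETA_DIVERGENCE:
            return beta, np.inf, False, n_iter
        if abs(delta) < _TOL:
            se = 1.0 / np.sqrt(info) if info > 0 else np.inf
            return beta, se, True, n_iter
    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    return beta, se, False, n_iter


def fit_cox_hr(
    table: pd.DataFrame,
    strain: str,
    ties: str = "efron",
    treated_arms: tuple = TREATED_ARMS,
) -> HazardEstimate:
    """Fit the arm hazard ratio for one strain.

    Parameters
    ----------
    table
        Survival records with columns ``strain``, ``arm``, ``time_h``,
        ``event`` (1 = death observed, 0 = right-censored).
    strain
        Strain to fit; both arms must be present.
    ties
        ``"efron"`` (default) or ``"breslow"``.

    Monotone likelihoods (all events in one arm, complete separation) are
    returned as flagged non-convergent estimates with an infinite log-HR
    bound rather than a silently finite number.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie correction {ties!r}")
    sub = table[table["strain"] == strain]
    if sub.empty:
        raise ValueError(f"strain {strain!r} absent from survival table")
    arms = set(sub["arm"])
    if CONTROL_ARM not in arms or not arms & set(treated_arms):
        raise ValueError(f"strain {strain!r} lacks one of the two arms")

    time = sub["time_h"].to_numpy(dtype=float)
    event = sub["event"].to_numpy(dtype=int)
    z = sub["arm"].isin(treated_arms).to_numpy(dtype=float)
    if (time <= 0).any():
        raise ValueError("event times must be positive")
    n_ev_t = int(event[z == 1].sum())
    n_ev_c = int(event[z == 0].sum())
    if n_ev_t + n_ev_c == 0:
        raise ValueError(f"strain {strain!r} has no events in either arm")

    if n_ev_t == 0 or n_ev_c == 0:
        # monotone partial likelihood: the MLE is at +/- infinity
        sign = 1.0 if n_ev_t > 0 else -1.0
        log.warning("strain %s: all events in one arm; estimate diverges", strain)
        return HazardEstimate(
            strain=strain,
            log_hr=sign * np.inf,
            hr=np.inf if sign > 0 else 0.0,
            se_log_hr=np.inf,
            wald_p=np.nan,
            n_events_treated=n_ev_t,
            n_events_control=n_ev_c,
            converged=False,
        )

    beta, se, converged, n_iter = _fit_cox_binary(time, event, z, ties)
    if not converged and abs(beta) > _BETA_DIVERGENCE:
        return HazardEstimate(
            strain=strain,
            log_hr=np.sign(beta) * np.inf,
            hr=np.inf if beta > 0 else 0.0,
            se_log_hr=np.inf,
            wald_p=np.nan,
            n_events_treated=n_ev_t,
            n_events_control=n_ev_c,
            converged=False,
            n_iter=n_iter,
        )
    wald_p = float(min(1.0, 2.0 * stats.norm.sf(abs(beta) / se))) if se > 0 else 1.0
    if beta == 0.0:
        wald_p = 1.0
    return HazardEstimate(
        strain=strain,
        log_hr=float(beta),
        hr=float(np.exp(beta)),
        se_log_hr=float(se),
        wald_p=wald_p,
        n_events_treated=n_ev_t,
        n_events_control=n_ev_c,
        converged=converged,
        n_iter=n_iter,
    )


def fit_all_strains(table: pd.DataFrame, ties: str = "efron") -> pd.DataFrame:
    """Fit every strain in the table; returns one row per strain."""
    rows = []
    for strain in sorted(table["strain"].unique()):
        est = fit_cox_hr(table, strain, ties=ties)
        rows.append(
            {
                "strain": est.strain,
                "hr": est.hr,
                "log_hr": est.log_hr,
                "se": est.se_log_hr,
                "p": est.wald_p,
                "n_events_treated": est.n_events_treated,
                "n_events_control": est.n_events_control,
                "converged": est.converged,
            }
        )
    return pd.DataFrame(rows)


def variance_ratio_test(hrs_a, hrs_b) -> tuple[float, float]:
    """Two-sided F test of equality of variances between two HR replicate sets.

    F = s2_a / s2_b on (n_a - 1, n_b - 1) degrees of freedom.  Performed on
    the scale the inputs arrive on (raw hazard ratios by convention here;
    pass logs for a log-scale test).
    """
    a = np.asarray(hrs_a, dtype=float)
    b = np.asarray(hrs_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each replicate vector needs length >= 2")
    s2a = a.var(ddof=1)
    s2b = b.var(ddof=1)
    if s2b == 0:
        raise ValueError("zero variance in denominator group")
    F = s2a / s2b
    dist = stats.f(a.size - 1, b.size - 1)
    p = 2.0 * min(dist.cdf(F), dist.sf(F))
    return float(F), float(min(1.0, p))


def correlate_phenotypes(
    hr_vector: pd.Series, other: pd.Series
) -> tuple[float, float, int]:
    """Pearson correlation between two per-strain phenotypes.

    Strains are inner-joined on their index; returns (r, two-sided P, n used).
    """
    joined = pd.concat(
        {"a": pd.Series(hr_vector), "b": pd.Series(other)}, axis=1, join="inner"
    ).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError(f"only {n} shared strains; need >= 3")
    r, p = stats.pearsonr(joined["a"], joined["b"])
    return float(r), float(p), n
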