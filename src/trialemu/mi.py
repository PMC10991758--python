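"""Multiple imputation of inflammatory markers and Rubin's-rules pooling.

Chained-equations imputation on the analysis scales (log CRP/LDH/D-dimer/
ferritin, square-root lymphocytes) with proper Bayesian linear-regression
draws: at each step the regression variance is drawn from its scaled
inverse-chi-square posterior, coefficients from their normal posterior, and
imputed values include residual noise.  Predictors are every other baseline
covariate, the currently imputed values of the other markers, event-type
indicators and the Nelson-Aalen cumulative all-cause hazard at the event
day, which carries the outcome information into the imputation model.

Pooling follows Rubin's rules with the Barnard-Rubin small-sample degrees of
freedom; log hazard ratios are pooled on the log scale and the interval
exponentiated afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import MARKERS

__all__ = ["ImputationSet", "impute", "PooledEstimate", "pool_rubin"]

_TRANSFORM = {
    "crp": (np.log, np.exp),
    "ldh": (np.log, np.exp),
    "ddimer": (np.log, np.exp),
    "lymph": (np.sqrt, np.square),
    "ferritin": (np.log, np.exp),
}


@dataclass
class ImputationSet:
    """m completed cohorts; non-missing values identical across copies."""

    cohorts: list[pd.DataFrame]
    m: int
    seed: int
    n_missing: dict[str, int]

    def __iter__(self):
        return iter(self.cohorts)


def _nelson_aalen(times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """All-cause Nelson-Aalen cumulative hazard evaluated at each time."""
    order = np.unique(times[events])
    cumhaz = {}
    h = 0.0
    for t in order:
        n_at_risk = (times >= t).sum()
        d = (events & (times == t)).sum()
        h += d / n_at_risk
        cumhaz[t] = h
    grid = np.array(sorted(cumhaz))
    vals = np.array([cumhaz[t] for t in grid])
    idx = np.searchsorted(grid, times, side="right")
    return np.concatenate([[0.0], vals])[idx]


def _predictor_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    times = cohort["event_day"].to_numpy(dtype=float)
    events = (cohort["event_type"] != "censored").to_numpy()
    out = pd.DataFrame(index=cohort.index)
    out["age"] = cohort["age"].astype(float)
    out["sex"] = cohort["sex"].astype(float)
    out["cci"] = cohort["cci"].astype(float)
    out["wave2"] = (cohort["wave"] == 2).astype(float)
    out["wave3"] = (cohort["wave"] == 3).astype(float)
    out["ev_death"] = (cohort["event_type"] == "death").astype(float)
    out["ev_home"] = (cohort["event_type"] == "home").astype(float)
    out["ev_transfer"] = (cohort["event_type"] == "transfer").astype(float)
    out["na_cumhaz"] = _nelson_aalen(times, events)
    return out


def _bayes_draw(y, X, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Draw (beta*, sigma*) from the posterior of a linear regression."""
    n, q = X.shape
    XtX = X.T @ X + 1e-8 * np.eye(q)
    beta_hat = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta_hat
    df = max(n - q, 1)
    sigma2 = resid @ resid / rng.chisquare(df)
    L = np.linalg.cholesky(np.linalg.inv(XtX))
    beta_star = beta_hat + np.sqrt(sigma2) * (L @ rng.standard_normal(q))
    return beta_star, float(np.sqrt(sigma2))


def impute(
    cohort: pd.DataFrame, m: int = 5, seed: int = 0, n_cycles: int = 10
) -> ImputationSet:
    """Multiply impute missing inflammatory-marker values.

    With no missing values the result is ``m`` identical copies, so a
    pipeline wrapped in imputation reduces exactly to the complete-data
    pipeline.
    """
    if m < 2:
        raise ValueError("m must be at least 2")
    miss = {mk: cohort[mk].isna().to_numpy() for mk in MARKERS}
    n_missing = {mk: int(v.sum()) for mk, v in miss.items()}
    if sum(n_missing.values()) == 0:
        return ImputationSet(
            cohorts=[cohort.copy() for _ in range(m)],
            m=m, seed=seed, n_missing=n_missing,
        )
    base_pred = _predictor_frame(cohort)
    # working matrix on transformed scales
    work0 = pd.DataFrame(
        {mk: _TRANSFORM[mk][0](cohort[mk].astype(float)) for mk in MARKERS}
    )
    for mk in MARKERS:
        if miss[mk].all():
            raise ValueError(f"marker {mk!r} is 100% missing")

    streams = np.random.SeedSequence(seed).spawn(m)
    cohorts = []
    for st in streams:
        rng = np.random.default_rng(st)
        work = work0.copy()
        # initialize missing entries with random observed draws
        for mk in MARKERS:
            if not miss[mk].any():
                continue
            obs = work[mk].dropna().to_numpy()
            work.loc[miss[mk], mk] = rng.choice(obs, size=miss[mk].sum())
        for _ in range(n_cycles):
            for mk in MARKERS:
                if not miss[mk].any():
                    continue
                others = [o for o in MARKERS if o != mk]
                X = np.column_stack(
                    [np.ones(len(cohort)), base_pred.to_numpy(),
                     work[others].to_numpy()]
                )
                y = work[mk].to_numpy()
                obs_mask = ~miss[mk]
                beta, sigma = _bayes_draw(y[obs_mask], X[obs_mask], rng)
                mu = X[miss[mk]] @ beta
                work.loc[miss[mk], mk] = mu + sigma * rng.standard_normal(
                    miss[mk].sum()
                )
        done = cohort.copy()
        for mk in MARKERS:
            back = _TRANSFORM[mk][1]
            filled = back(work[mk].to_numpy())
            col = done[mk].to_numpy(dtype=float)
            col[miss[mk]] = filled[miss[mk]]
            done[mk] = col
        cohorts.append(done)
    return ImputationSet(cohorts=cohorts, m=m, seed=seed, n_missing=n_missing)


# --------------------------------------------------------------------------
# pooling


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of m estimates."""

    estimate: float
    within: float
    between: float
    total: float
    df: float
    se: float
    ci_low: float
    ci_high: float
    m: int

    def hazard_ratio(self) -> tuple[float, float, float]:
        """Exponentiate a pooled log-HR and its CI."""
        return (
            float(np.exp(self.estimate)),
            float(np.exp(self.ci_low)),
            float(np.exp(self.ci_high)),
        )


def pool_rubin(
    estimates, variances, df_complete: float = np.inf, alpha: float = 0.05
) -> PooledEstimate:
    """Combine per-imputation estimates and variances.

    Total variance T = W + (1 + 1/m) B; interval uses the Barnard-Rubin
    degrees of freedom when ``df_complete`` is finite, else the classical
    Rubin df.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape:
        raise ValueError("estimates and variances must have equal length")
    m = len(q)
    if m < 2:
        raise ValueError("need at least 2 imputations to pool")
    qbar = float(q.mean())
    W = float(u.mean())
    B = float(q.var(ddof=1))
    T = W + (1.0 + 1.0 / m) * B
    if B <= 0 or T <= 0:
        df = np.inf
    else:
        lam = (1.0 + 1.0 / m) * B / T
        df_old = (m - 1) / lam**2
        if np.isfinite(df_complete):
            df_obs = (
                (df_complete + 1.0) / (df_complete + 3.0)
                * df_complete * (1.0 - lam)
            )
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        else:
            df = df_old
    se = float(np.sqrt(T))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df) if np.isfinite(df) else (
        stats.norm.ppf(1.0 - alpha / 2.0)
    )
    return PooledEstimate(
        estimate=qbar, within=W, between=B, total=T, df=float(df), se=se,
        ci_low=qbar - tcrit * se, ci_high=qbar + tcrit * se, m=m,
    )
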