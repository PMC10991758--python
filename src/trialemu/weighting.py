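"""Propensity-score IPTW, inverse-probability-of-censoring weights for the
clone-censor-weight emulation, and covariate-balance diagnostics.

The propensity model targets the probability of *ever* receiving the
treatment given baseline covariates; its stabilized inverse-probability
weights feed the weighted time-dependent Cox model.  The censoring model for
the emulation is a discrete-time (daily) logistic model of remaining
artificially uncensored during the grace window, fitted separately per day
within each arm — the saturated-in-time version of a pooled daily logistic
model, natural when the grace window spans only a couple of days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Logistic", "LogisticResults", "fit_logistic", "iptw_weights",
    "ipcw_artificial_censoring", "standardized_differences", "SeparationError",
]


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE does not exist."""


@dataclass
class LogisticResults:
    """Maximum-likelihood logistic regression fit (IRLS)."""

    params: np.ndarray          # intercept first
    names: list[str]
    fitted: np.ndarray          # per-observation probabilities
    cov: np.ndarray
    loglik: float
    n_iter: int
    converged: bool

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = np.column_stack([np.ones(len(X)), X])
        return _expit(Z @ self.params)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


class Logistic:
    """Binary logistic regression fitted by iteratively reweighted least
    squares, with explicit detection of (quasi-)separation."""

    def __init__(self, y, X, names: list[str] | None = None, weights=None):
        self.y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.X = X
        self.w = np.ones(len(self.y)) if weights is None else np.asarray(
            weights, dtype=float
        )
        self.names = names or [f"x{i}" for i in range(X.shape[1])]
        if not set(np.unique(self.y)) <= {0.0, 1.0}:
            raise ValueError("outcome must be binary 0/1")
        if self.y.min() == self.y.max():
            raise ValueError("both outcome classes must be present")

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> LogisticResults:
        Z = np.column_stack([np.ones(len(self.y)), self.X])
        # standardize non-intercept columns for stable IRLS
        mean = Z[:, 1:].mean(axis=0)
        sd = Z[:, 1:].std(axis=0)
        if np.any(sd <= 0):
            raise ValueError("constant covariate column")
        Zs = Z.copy()
        Zs[:, 1:] = (Z[:, 1:] - mean) / sd
        beta = np.zeros(Z.shape[1])
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            p = _expit(Zs @ beta)
            grad = Zs.T @ (self.w * (self.y - p))
            W = self.w * p * (1.0 - p)
            H = Zs.T @ (W[:, None] * Zs)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError as exc:
                raise SeparationError(
                    "singular information matrix (separation or collinearity)"
                ) from exc
            beta = beta + step
            # on the standardized scale a slope beyond ~15 means fitted
            # probabilities saturate at 0/1: the MLE is diverging
            if (beta.size > 1 and np.abs(beta[1:]).max() > 15.0) or abs(
                beta[0]
            ) > 40.0:
                raise SeparationError(
                    "diverging coefficients: data are (quasi-)separated"
                )
            if np.linalg.norm(grad) < tol:
                converged = True
                break
        if not converged:
            raise SeparationError(
                "IRLS did not converge: data are likely (quasi-)separated"
            )
        p = _expit(Zs @ beta)
        ll = float(
            np.sum(
                self.w
                * (self.y * np.log(np.maximum(p, 1e-300))
                   + (1 - self.y) * np.log(np.maximum(1 - p, 1e-300)))
            )
        )
        W = self.w * p * (1.0 - p)
        cov_s = np.linalg.inv(Zs.T @ (W[:, None] * Zs))
        # back-transform to original scale
        T = np.eye(Z.shape[1])
        T[0, 1:] = -mean / sd
        for j in range(1, Z.shape[1]):
            T[j, j] = 1.0 / sd[j - 1]
        beta_orig = T @ beta
        cov = T @ cov_s @ T.T
        return LogisticResults(
            params=beta_orig,
            names=["intercept", *self.names],
            fitted=_expit(Z @ beta_orig),
            cov=cov,
            loglik=ll,
            n_iter=it,
            converged=converged,
        )


def fit_logistic(y, X, names: list[str] | None = None, weights=None) -> LogisticResults:
    """IRLS maximum-likelihood logistic regression (intercept added)."""
    return Logistic(y, X, names=names, weights=weights).fit()


# --------------------------------------------------------------------------
# inverse probability of treatment weights


def iptw_weights(
    model: LogisticResults,
    treated,
    stabilized: bool = True,
    truncation_percentile: float = 99.0,
) -> np.ndarray:
    """Inverse-probability-of-treatment weights from a fitted propensity model.

    Stabilized weights use the marginal treated fraction in the numerator and
    have mean approximately 1; weights above the given percentile are capped.
    """
    treated = np.asarray(treated, dtype=bool)
    ps = np.clip(model.fitted, 1e-6, 1.0 - 1e-6)
    marginal = treated.mean()
    if stabilized:
        w = np.where(treated, marginal / ps, (1.0 - marginal) / (1.0 - ps))
    else:
        w = np.where(treated, 1.0 / ps, 1.0 / (1.0 - ps))
    if truncation_percentile < 100.0:
        cap = np.percentile(w, truncation_percentile)
        w = np.minimum(w, cap)
    return w


# --------------------------------------------------------------------------
# inverse probability of (artificial) censoring weights


def ipcw_artificial_censoring(
    clones: pd.DataFrame,
    covariate_cols: list[str],
    grace: int,
    truncation_percentile: float = 99.0,
    arm_col: str = "arm",
    end_col: str = "clone_end",
    acens_col: str = "artificial_censor_day",
) -> np.ndarray:
    """Per-clone weight trajectory over days 1..grace, shape (n_clones, grace).

    Within each arm and for each day s in the grace window, a logistic model
    of being artificially censored on day s is fitted among clones still
    under follow-up at the start of day s, excluding clones whose terminal
    event falls on day s (events precede the end-of-day censoring decision,
    so those clones were never censorable).  The clone weight at day t is
    1 / prod_{s<=min(t,grace)} P(uncensored at s | covariates, arm); weights
    are constant after the grace window and capped at the requested
    percentile of the day-`grace` weights within each arm.  Days on which an
    arm has no artificial censoring contribute probability one.
    """
    return _ipcw_core(
        clones[arm_col].to_numpy(),
        clones[end_col].to_numpy(dtype=float),
        clones[acens_col].to_numpy(dtype=float),
        clones[covariate_cols].to_numpy(dtype=float),
        grace,
        truncation_percentile,
    )


def _ipcw_core(arms, end, acens, X, grace, truncation_percentile=99.0):
    n = len(end)
    cum = np.ones((n, grace))
    for arm in np.unique(arms):
        in_arm = arms == arm
        if np.isnan(acens[in_arm]).all():
            continue  # no artificial censoring in this arm: weights all 1
        prob_uncens = np.ones((int(in_arm.sum()), grace))
        Xa = X[in_arm]
        end_a = end[in_arm]
        ac_a = acens[in_arm]
        for day in range(1, grace + 1):
            cens_today = np.where(np.isnan(ac_a), False, ac_a == day)
            # clones with an *event* on this day are not censorable: events
            # precede the end-of-day censoring decision
            at_risk = (end_a > day) | cens_today
            if not cens_today.any():
                continue
            if cens_today[at_risk].all():
                raise ValueError(
                    f"arm {arm!r}: every at-risk clone censored on day {day}"
                )
            y = cens_today[at_risk].astype(float)
            try:
                res = fit_logistic(y, Xa[at_risk])
                p_cens = res.predict(Xa)
            except (SeparationError, ValueError):
                # fall back to the marginal daily censoring probability
                p_cens = np.full(len(Xa), y.mean())
            prob_uncens[at_risk, day - 1] = 1.0 - np.clip(
                p_cens[at_risk], 0.0, 1.0 - 1e-12
            )
        cum[in_arm] = 1.0 / np.cumprod(prob_uncens, axis=1)
        if truncation_percentile < 100.0:
            cap = np.percentile(cum[in_arm, -1], truncation_percentile)
            cum[in_arm] = np.minimum(cum[in_arm], max(cap, 1.0))
    return cum


# --------------------------------------------------------------------------
# balance diagnostics


def standardized_differences(
    data: pd.DataFrame,
    covariates: list[str],
    group_col: str,
    weights=None,
) -> pd.Series:
    """Standardized mean differences between two groups.

    SMD = (mean1 - mean0) / sqrt((var1 + var0) / 2), with weighted moments
    when weights are given.  Binary covariates use the proportion-based
    variance p(1-p).
    """
    groups = data[group_col].to_numpy()
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    w = np.ones(len(data)) if weights is None else np.asarray(weights, dtype=float)
    out = {}
    for cov in covariates:
        x = data[cov].to_numpy(dtype=float)
        stats = []
        for g in levels:
            m = groups == g
            mu = np.average(x[m], weights=w[m])
            binary = set(np.unique(x)) <= {0.0, 1.0}
            if binary:
                var = mu * (1.0 - mu)
            else:
                var = np.average((x[m] - mu) ** 2, weights=w[m])
            stats.append((mu, var))
        (mu0, v0), (mu1, v1) = stats
        pooled = np.sqrt((v0 + v1) / 2.0)
        if pooled == 0:
            if mu0 == mu1:
                out[cov] = 0.0
                continue
            raise ValueError(f"zero pooled variance for {cov!r}")
        out[cov] = (mu1 - mu0) / pooled
    return pd.Series(out)
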