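"""Cox proportional-hazards engine for start-stop data.

Newton-Raphson maximization of the (case-weighted) partial likelihood over
risk sets defined by ``start < t <= stop``, with Efron (default) or Breslow
handling of tied event times, optional per-interval weights, and a
cluster-robust sandwich variance built from score residuals grouped by
patient (all intervals and clones of one patient share a group).

Daily event grids produce many ties, which is why Efron is the default;
Breslow is retained because its simpler likelihood is convenient for
brute-force verification.  Covariates are standardized internally for
numerical stability and results are reported on the original scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoxTimeVarying", "CoxResults", "fit_cox", "hazard_ratio",
    "score_test_null", "ConvergenceError",
]

_BETA_CAP = 20.0     # hard cap on the standardized scale
_BETA_DETECT = 10.0  # |beta_std| beyond this flags a monotone likelihood


class ConvergenceError(RuntimeError):
    """Raised when the partial likelihood cannot be maximized."""


@dataclass
class CoxResults:
    """Fitted log hazard ratios with model-based and robust variances."""

    params: pd.Series
    cov: pd.DataFrame
    robust_cov: pd.DataFrame | None
    loglik: float
    n_iter: int
    converged: bool
    ties: str
    n_events: int
    n_obs: int
    monotone: pd.Series  # per-coefficient flag: likelihood monotone, capped

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    @property
    def robust_bse(self) -> pd.Series | None:
        if self.robust_cov is None:
            return None
        return pd.Series(
            np.sqrt(np.diag(self.robust_cov)), index=self.params.index
        )

    def _se(self, robust: bool = True) -> pd.Series:
        if robust and self.robust_cov is not None:
            return self.robust_bse
        return self.bse

    def hazard_ratio(
        self, name: str, robust: bool = True, alpha: float = 0.05
    ) -> tuple[float, float, float]:
        """(HR, CI low, CI high) via the Wald interval exp(b +/- z*SE)."""
        if name not in self.params.index:
            raise KeyError(f"unknown coefficient {name!r}")
        b = self.params[name]
        se = self._se(robust)[name]
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return float(np.exp(b)), float(np.exp(b - z * se)), float(np.exp(b + z * se))

    def summary(self, robust: bool = True) -> pd.DataFrame:
        se = self._se(robust)
        z = self.params / se
        hr = np.exp(self.params)
        lo = np.exp(self.params - 1.959963984540054 * se)
        hi = np.exp(self.params + 1.959963984540054 * se)
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "coef": self.params, "se": se, "z": z, "p": p,
                "HR": hr, "HR 95% low": lo, "HR 95% high": hi,
            }
        )

    def to_dict(self) -> dict:
        out = {
            "ties": self.ties,
            "loglik": self.loglik,
            "n_events": self.n_events,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "coefficients": {},
        }
        for name in self.params.index:
            hr, lo, hi = self.hazard_ratio(name)
            out["coefficients"][name] = {
                "coef": float(self.params[name]),
                "se": float(self.bse[name]),
                "robust_se": (
                    float(self.robust_bse[name])
                    if self.robust_cov is not None else None
                ),
                "HR": hr, "CI_low": lo, "CI_high": hi,
            }
        return out


# --------------------------------------------------------------------------
# numerical core (arrays only, standardized scale)


def _loglik_terms(start, stop, event, X, w, beta, ties, want_hess=True):
    """Log partial likelihood, gradient and Hessian at beta."""
    p = X.shape[1]
    eta = X @ beta
    eta = np.clip(eta, -300, 300)
    r = w * np.exp(eta)
    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    ev_times = np.unique(stop[event])
    for t in ev_times:
        risk = (start < t) & (stop >= t)
        dead = event & (stop == t)
        rw = r[risk]
        Xr = X[risk]
        S0 = rw.sum()
        S1 = rw @ Xr
        if want_hess:
            S2 = Xr.T @ (rw[:, None] * Xr)
        WD = w[dead].sum()
        loglik += float(w[dead] @ eta[dead])
        sumx = w[dead] @ X[dead]
        if ties == "breslow":
            loglik -= WD * np.log(S0)
            grad += sumx - WD * S1 / S0
            if want_hess:
                hess += WD * (S2 / S0 - np.outer(S1, S1) / S0**2)
        else:  # efron
            m = int(dead.sum())
            rd = r[dead]
            S0D = rd.sum()
            S1D = rd @ X[dead]
            if want_hess:
                S2D = X[dead].T @ (rd[:, None] * X[dead])
            fr = np.arange(m) / m
            S0k = S0 - fr * S0D  # (m,)
            loglik -= (WD / m) * np.log(S0k).sum()
            xbar_k = (S1[None, :] - fr[:, None] * S1D) / S0k[:, None]  # (m, p)
            grad += sumx - (WD / m) * xbar_k.sum(axis=0)
            if want_hess:
                inv = 1.0 / S0k
                M2 = S2 * inv.sum() - S2D * (fr * inv).sum()
                hess += (WD / m) * (M2 - xbar_k.T @ xbar_k)
    return loglik, grad, hess


def _loglik_1d_grid(start, stop, event, x, w, beta, ties):
    """Single-covariate likelihood terms on an integer day grid.

    Equivalent to :func:`_loglik_terms` with p = 1, but risk-set sums are
    accumulated with difference arrays over the day grid instead of per-time
    masks, which makes the bootstrap loop fast.
    """
    T = int(stop.max())
    eta = np.clip(x * beta, -300, 300)
    r = w * np.exp(eta)
    rx = r * x
    rxx = rx * x
    si = start.astype(np.int64)
    ti = stop.astype(np.int64)

    def risk_cum(v):
        diff = np.bincount(si + 1, weights=v, minlength=T + 2)
        diff -= np.bincount(ti + 1, weights=v, minlength=T + 2)
        return np.cumsum(diff)[1 : T + 1]  # index t-1 -> sum over start<t<=stop

    S0 = risk_cum(r)
    S1 = risk_cum(rx)
    S2 = risk_cum(rxx)
    td = ti[event]
    mcnt = np.bincount(td, minlength=T + 1)[1:]
    WD = np.bincount(td, weights=w[event], minlength=T + 1)[1:]
    sumx = np.bincount(td, weights=(w * x)[event], minlength=T + 1)[1:]
    sum_eta = np.bincount(td, weights=(w * eta)[event], minlength=T + 1)[1:]
    ev = mcnt > 0
    loglik = float(sum_eta.sum())
    if ties == "breslow":
        loglik -= float(WD[ev] @ np.log(S0[ev]))
        xbar = S1[ev] / S0[ev]
        grad = float(sumx[ev].sum() - WD[ev] @ xbar)
        hess = float(WD[ev] @ (S2[ev] / S0[ev] - xbar**2))
        return loglik, grad, hess
    S0D = np.bincount(td, weights=r[event], minlength=T + 1)[1:]
    S1D = np.bincount(td, weights=rx[event], minlength=T + 1)[1:]
    S2D = np.bincount(td, weights=rxx[event], minlength=T + 1)[1:]
    grad = float(sumx[ev].sum())
    hess = 0.0
    for t in np.flatnonzero(ev):
        m = mcnt[t]
        fr = np.arange(m) / m
        S0k = S0[t] - fr * S0D[t]
        loglik -= (WD[t] / m) * float(np.log(S0k).sum())
        xbar_k = (S1[t] - fr * S1D[t]) / S0k
        grad -= (WD[t] / m) * float(xbar_k.sum())
        hess += (WD[t] / m) * float(
            ((S2[t] - fr * S2D[t]) / S0k - xbar_k**2).sum()
        )
    return loglik, grad, hess


def _newton_1d_grid(start, stop, event, x, w, ties, tol=1e-9, max_iter=50):
    """Scalar Newton on the day-grid likelihood; returns (beta, var, ok)."""
    beta = 0.0
    ll, grad, hess = _loglik_1d_grid(start, stop, event, x, w, 0.0, ties)
    if hess <= 0:
        raise ConvergenceError("degenerate covariate")
    converged = False
    for _ in range(max_iter):
        step = grad / hess
        scale = 1.0
        for _ in range(25):
            cand = float(np.clip(beta + scale * step, -_BETA_CAP, _BETA_CAP))
            ll_new, grad_new, hess_new = _loglik_1d_grid(
                start, stop, event, x, w, cand, ties
            )
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        rel = abs(ll_new - ll) / (abs(ll) + 1.0)
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if rel < tol:
            converged = True
            break
    return beta, 1.0 / hess, converged


def _score_residuals(start, stop, event, X, w, beta, ties):
    """Per-record score residuals; they sum to the gradient."""
    n, p = X.shape
    eta = np.clip(X @ beta, -300, 300)
    r = w * np.exp(eta)
    resid = np.zeros((n, p))
    ev_times = np.unique(stop[event])
    for t in ev_times:
        risk = (start < t) & (stop >= t)
        dead = event & (stop == t)
        rw = r[risk]
        Xr = X[risk]
        S0 = rw.sum()
        S1 = rw @ Xr
        WD = w[dead].sum()
        if ties == "breslow":
            xbar = S1 / S0
            resid[dead] += w[dead, None] * (X[dead] - xbar)
            A, B = WD / S0, (WD / S0) * xbar
            resid[risk] -= r[risk, None] * (A * Xr - B)
        else:
            m = int(dead.sum())
            rd = r[dead]
            S0D = rd.sum()
            S1D = rd @ X[dead]
            fr = np.arange(m) / m
            S0k = S0 - fr * S0D
            xbar_k = (S1[None, :] - fr[:, None] * S1D) / S0k[:, None]
            resid[dead] += w[dead, None] * (X[dead] - xbar_k.mean(axis=0))
            inv = 1.0 / S0k
            A = (WD / m) * inv.sum()
            B = (WD / m) * (xbar_k * inv[:, None]).sum(axis=0)
            Ad = (WD / m) * ((1.0 - fr) * inv).sum()
            Bd = (WD / m) * ((1.0 - fr)[:, None] * xbar_k * inv[:, None]).sum(axis=0)
            resid[risk] -= r[risk, None] * (A * Xr - B)
            resid[dead] -= r[dead, None] * ((Ad - A) * X[dead] - (Bd - B))
    return resid


def _newton(start, stop, event, X, w, ties, tol=1e-9, max_iter=50):
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _loglik_terms(start, stop, event, X, w, beta, ties)
    try:
        cond = np.linalg.cond(hess)
    except np.linalg.LinAlgError:  # pragma: no cover
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        raise ConvergenceError(
            "degenerate covariate: no variation within any risk set"
        )
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        step = np.linalg.solve(hess, grad)
        new_beta = beta + step
        scale = 1.0
        for _ in range(25):
            cand = np.clip(new_beta, -_BETA_CAP, _BETA_CAP)
            ll_new, grad_new, hess_new = _loglik_terms(
                start, stop, event, X, w, cand, ties
            )
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
            new_beta = beta + scale * step
        else:  # pragma: no cover
            break
        rel = abs(ll_new - ll) / (abs(ll) + 1.0)
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if rel < tol:
            converged = True
            break
    monotone = np.abs(beta) >= _BETA_DETECT
    if monotone.any():
        import warnings

        warnings.warn(
            "monotone partial likelihood: coefficient(s) diverging, "
            "estimate capped",
            RuntimeWarning,
            stacklevel=3,
        )
    return beta, ll, grad, hess, it, converged, monotone


# --------------------------------------------------------------------------
# model class


class CoxTimeVarying:
    """Cox model on counting-process rows.

    Parameters
    ----------
    rows : DataFrame with ``start``, ``stop``, a binary event column, the
        covariates, optionally ``weight`` and a cluster id column.
    covariates : names of covariate columns.
    event_col : binary event indicator at ``stop`` (build with
        :func:`trialemu.data.cause_specific_view`).
    cluster_col : grouping for the robust variance (default ``patient_id``).
    """

    def __init__(
        self,
        rows: pd.DataFrame,
        covariates: list[str],
        event_col: str = "event",
        start_col: str = "start",
        stop_col: str = "stop",
        weight_col: str | None = "weight",
        cluster_col: str | None = "patient_id",
    ):
        self.covariates = list(covariates)
        self.start = rows[start_col].to_numpy(dtype=float)
        self.stop = rows[stop_col].to_numpy(dtype=float)
        if np.any(self.start >= self.stop):
            raise ValueError("intervals must satisfy start < stop")
        self.event = rows[event_col].to_numpy().astype(bool)
        self.X = rows[self.covariates].to_numpy(dtype=float)
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite covariate values")
        if weight_col is not None and weight_col in rows.columns:
            self.w = rows[weight_col].to_numpy(dtype=float)
            if np.any(self.w < 0):
                raise ValueError("negative weights")
        else:
            self.w = np.ones(len(rows))
        if cluster_col is not None and cluster_col in rows.columns:
            self.groups = rows[cluster_col].to_numpy()
        else:
            self.groups = np.arange(len(rows))

    def fit(
        self,
        ties: str = "efron",
        robust: bool = True,
        use_weights: bool = True,
        tol: float = 1e-9,
        max_iter: int = 50,
    ) -> CoxResults:
        if ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        if not self.event.any():
            raise ValueError("no events in the data")
        w = self.w if use_weights else np.ones_like(self.w)
        # standardize (weighted) for numerical stability
        mean = np.average(self.X, axis=0, weights=np.maximum(w, 1e-300))
        sd = np.sqrt(
            np.average((self.X - mean) ** 2, axis=0, weights=np.maximum(w, 1e-300))
        )
        if np.any(sd <= 0):
            bad = [self.covariates[i] for i in np.flatnonzero(sd <= 0)]
            raise ConvergenceError(f"degenerate covariate(s): {bad}")
        Xs = (self.X - mean) / sd

        beta_s, ll, grad, hess, it, converged, monotone = _newton(
            self.start, self.stop, self.event, Xs, w, ties, tol, max_iter
        )
        cov_s = np.linalg.inv(hess)
        beta = beta_s / sd
        cov = cov_s / np.outer(sd, sd)

        robust_cov = None
        if robust:
            U = _score_residuals(
                self.start, self.stop, self.event, Xs, w, beta_s, ties
            )
            dfU = pd.DataFrame(U)
            dfU["_g"] = self.groups
            Ug = dfU.groupby("_g", sort=False).sum().to_numpy()
            meat = Ug.T @ Ug
            rob_s = cov_s @ meat @ cov_s
            robust_cov = rob_s / np.outer(sd, sd)

        idx = pd.Index(self.covariates)
        return CoxResults(
            params=pd.Series(beta, index=idx),
            cov=pd.DataFrame(cov, index=idx, columns=idx),
            robust_cov=(
                pd.DataFrame(robust_cov, index=idx, columns=idx)
                if robust_cov is not None else None
            ),
            loglik=float(ll),
            n_iter=it,
            converged=bool(converged),
            ties=ties,
            n_events=int(self.event.sum()),
            n_obs=len(self.start),
            monotone=pd.Series(monotone, index=idx),
        )


def fit_cox(
    rows: pd.DataFrame,
    covariates: list[str],
    ties: str = "efron",
    use_weights: bool = True,
    robust: bool = True,
    event_col: str = "event",
    cluster_col: str | None = "patient_id",
) -> CoxResults:
    """Functional entry point for :class:`CoxTimeVarying`."""
    model = CoxTimeVarying(
        rows, covariates, event_col=event_col, cluster_col=cluster_col
    )
    return model.fit(ties=ties, robust=robust, use_weights=use_weights)


def hazard_ratio(fit: CoxResults, name: str) -> tuple[float, float, float]:
    """Exponentiated coefficient with its Wald 95% CI (robust SE if any)."""
    return fit.hazard_ratio(name)


def score_test_null(
    rows: pd.DataFrame,
    covariate: str,
    ties: str = "efron",
    event_col: str = "event",
) -> float:
    """Score (log-rank type) statistic for H0: beta = 0, chi^2(1) reference."""
    model = CoxTimeVarying(rows, [covariate], event_col=event_col)
    w = model.w
    mean = np.average(model.X, axis=0, weights=np.maximum(w, 1e-300))
    sd = np.sqrt(
        np.average((model.X - mean) ** 2, axis=0, weights=np.maximum(w, 1e-300))
    )
    if np.any(sd <= 0):
        raise ConvergenceError("degenerate covariate")
    Xs = (model.X - mean) / sd
    _, grad, hess = _loglik_terms(
        model.start, model.stop, model.event, Xs, w, np.zeros(1), ties
    )
    return float(grad[0] ** 2 / hess[0, 0])
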