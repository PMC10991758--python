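"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations — explicit day-by-day risk-set
bookkeeping, fully enumerated partial likelihoods maximized by 1-D search —
kept free of any code from the package's estimation paths.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize_scalar


def occupancy_cif(times, causes, weights=None, max_day=None):
    """Day-by-day multi-state occupancy bookkeeping.

    Returns (days, survival, {cause: cif}) evaluated at integer days
    1..max_day for integer-day data; causes use "none" for censoring.
    """
    times = [float(t) for t in times]
    causes = list(causes)
    n = len(times)
    w = [1.0] * n if weights is None else [float(x) for x in weights]
    if max_day is None:
        max_day = int(max(times))
    labels = sorted({c for c in causes if c not in ("none", "censored")}, key=str)
    surv = 1.0
    cif = {c: 0.0 for c in labels}
    out_s, out_c = [], []
    for day in range(1, max_day + 1):
        at_risk = sum(w[i] for i in range(n) if times[i] >= day)
        d = {
            c: sum(
                w[i] for i in range(n) if times[i] == day and causes[i] == c
            )
            for c in labels
        }
        total = sum(d.values())
        if total > 0 and at_risk > 0:
            for c in labels:
                cif[c] += surv * d[c] / at_risk
            surv *= 1.0 - total / at_risk
        out_s.append(surv)
        out_c.append(dict(cif))
    days = list(range(1, max_day + 1))
    return days, out_s, out_c


def km_oracle(times, status, weights=None, max_day=None):
    """Day-grid product-limit survival via the occupancy oracle."""
    causes = ["event" if s else "none" for s in status]
    days, surv, _ = occupancy_cif(times, causes, weights, max_day)
    return days, surv


# --------------------------------------------------------------------------
# partial likelihoods, fully enumerated


def breslow_loglik(start, stop, event, x, w, beta):
    ll = 0.0
    ev_times = sorted({stop[i] for i in range(len(stop)) if event[i]})
    for t in ev_times:
        denom = sum(
            w[i] * math.exp(beta * x[i])
            for i in range(len(stop))
            if start[i] < t <= stop[i]
        )
        for i in range(len(stop)):
            if event[i] and stop[i] == t:
                ll += w[i] * (beta * x[i] - math.log(denom))
    return ll


def efron_loglik(start, stop, event, x, w, beta):
    ll = 0.0
    ev_times = sorted({stop[i] for i in range(len(stop)) if event[i]})
    for t in ev_times:
        risk = [i for i in range(len(stop)) if start[i] < t <= stop[i]]
        dead = [i for i in risk if event[i] and stop[i] == t]
        m = len(dead)
        s0 = sum(w[i] * math.exp(beta * x[i]) for i in risk)
        s0d = sum(w[i] * math.exp(beta * x[i]) for i in dead)
        wd = sum(w[i] for i in dead)
        for i in dead:
            ll += w[i] * beta * x[i]
        for k in range(m):
            ll -= (wd / m) * math.log(s0 - (k / m) * s0d)
    return ll


def maximize_partial_likelihood(loglik, start, stop, event, x, w,
                                bounds=(-8.0, 8.0)):
    """Golden-section/Brent search of a 1-D partial likelihood."""
    res = minimize_scalar(
        lambda b: -loglik(start, stop, event, x, w, b),
        bounds=bounds,
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def logistic_loglik(y, x, a, b):
    ll = 0.0
    for yi, xi in zip(y, x):
        eta = a + b * xi
        p = 1.0 / (1.0 + math.exp(-eta))
        ll += yi * math.log(p) + (1 - yi) * math.log(1 - p)
    return ll


def random_competing_dataset(rng, n_max=20, t_max=9):
    """Small random integer-day competing-risks dataset."""
    n = int(rng.integers(2, n_max + 1))
    times = rng.integers(1, t_max + 1, n).astype(float)
    causes = rng.choice(
        ["death", "home", "transfer", "none"], size=n, p=[0.35, 0.25, 0.15, 0.25]
    )
    weights = rng.choice([1.0, 1.0, 2.0, 3.0], size=n)
    return times, causes, weights
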