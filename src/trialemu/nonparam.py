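"""Weighted product-limit and multi-state nonparametric estimators.

Implements the Kaplan-Meier survival estimator, the (deliberately biased)
one-minus-Kaplan-Meier "cumulative incidence" that treats competing events as
censoring, and the Aalen-Johansen estimator of cause-specific cumulative
incidence functions.  All estimators accept observation weights and optional
late-entry times, so they can be driven directly by counting-process rows
with time-varying inverse-probability weights (the weighted Aalen-Johansen
used in the emulated trial).

Tie convention: risk sets are {i : entry_i < t <= stop_i}, so at a day where
an event and a censoring coincide the censored record is still at risk —
events precede censorings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StepCurve", "CIFSet", "kaplan_meier", "one_minus_km",
    "aalen_johansen", "curve_at",
]

#: cause labels interpreted as "no event"
CENSORED_LABELS = frozenset({"none", "censored", "", 0, None})


@dataclass
class StepCurve:
    """A right-continuous step function given by jump times and post-jump
    values, plus the value before the first jump."""

    times: np.ndarray
    values: np.ndarray
    initial: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("jump times must be strictly increasing")
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")

    def __call__(self, t) -> np.ndarray | float:
        return curve_at(self, t)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, "value": self.values})


def curve_at(curve: StepCurve, t) -> np.ndarray | float:
    """Right-continuous evaluation of a step curve at time(s) ``t``."""
    t_arr = np.asarray(t, dtype=float)
    idx = np.searchsorted(curve.times, t_arr, side="right")
    padded = np.concatenate([[curve.initial], curve.values])
    out = padded[idx]
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


@dataclass
class CIFSet:
    """Per-cause cumulative incidence curves plus overall event-free survival.

    Invariant: at every time, sum of CIFs plus survival equals one.
    """

    cifs: dict[str, StepCurve] = field(default_factory=dict)
    survival: StepCurve | None = None

    def check(self, atol: float = 1e-10) -> None:
        if self.survival is None:
            return
        t = self.survival.times
        total = curve_at(self.survival, t)
        for c in self.cifs.values():
            total = total + curve_at(c, t)
        if t.size and np.max(np.abs(total - 1.0)) > atol:
            raise AssertionError("CIFs and survival do not sum to 1")


def _prepare(times, weights, entry):
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("all stop times must be positive")
    w = np.ones_like(times) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("negative weight")
    e = np.zeros_like(times) if entry is None else np.asarray(entry, dtype=float)
    if np.any(e >= times):
        raise ValueError("entry must precede stop time")
    return times, w, e


def _is_event(cause_status) -> np.ndarray:
    arr = np.asarray(cause_status, dtype=object)
    return np.array([c not in CENSORED_LABELS for c in arr])


def kaplan_meier(times, status, weights=None, entry=None) -> StepCurve:
    """Weighted product-limit estimate of the survival function.

    ``status`` is 1/True for an event at the stop time, 0/False for a
    censoring.  With all weights equal this is the classical Kaplan-Meier
    estimator; weights enter both the event counts and the risk sets.
    """
    times, w, e = _prepare(times, weights, entry)
    status = np.asarray(status).astype(bool)
    ev_times = np.unique(times[status & (w > 0)])
    surv = 1.0
    out_t, out_v = [], []
    for t in ev_times:
        at_risk = (e < t) & (times >= t)
        n = w[at_risk].sum()
        d = w[status & (times == t)].sum()
        if n <= 0:
            raise ValueError(f"empty risk set at event time {t}")
        surv *= 1.0 - d / n
        out_t.append(t)
        out_v.append(surv)
    return StepCurve(np.array(out_t), np.array(out_v), initial=1.0)


def one_minus_km(
    times, cause_status, target_cause, weights=None, entry=None
) -> StepCurve:
    """1 - KM for one cause, treating competing events as right-censored.

    This is the naive estimator: it overstates the cumulative incidence of
    the target cause whenever competing events are present.
    """
    arr = np.asarray(cause_status, dtype=object)
    status = np.array([c == target_cause for c in arr])
    km = kaplan_meier(times, status, weights=weights, entry=entry)
    return StepCurve(km.times, 1.0 - km.values, initial=0.0)


def aalen_johansen(times, cause_status, weights=None, entry=None) -> CIFSet:
    """Weighted Aalen-Johansen estimator of cause-specific CIFs.

    ``cause_status`` holds a cause label per row, with "none"/"censored"
    (or 0/None/"") meaning no event.  Rows may describe (entry, stop]
    intervals of a single subject with differing weights, which is how
    time-varying inverse-probability weights enter.
    """
    times, w, e = _prepare(times, weights, entry)
    arr = np.asarray(cause_status, dtype=object)
    is_event = _is_event(arr)
    causes = sorted({c for c in arr[is_event]}, key=str)
    ev_times = np.unique(times[is_event & (w > 0)])

    surv = 1.0
    cif = {c: 0.0 for c in causes}
    out_t = []
    out_surv = []
    out_cif = {c: [] for c in causes}
    for t in ev_times:
        at_risk = (e < t) & (times >= t)
        n = w[at_risk].sum()
        if n <= 0:
            raise ValueError(f"empty risk set at event time {t}")
        total_haz = 0.0
        for c in causes:
            d = w[is_event & (times == t) & (arr == c)].sum()
            haz = d / n
            cif[c] += surv * haz
            total_haz += haz
        surv *= 1.0 - total_haz
        out_t.append(t)
        out_surv.append(surv)
        for c in causes:
            out_cif[c].append(cif[c])

    t_arr = np.array(out_t)
    result = CIFSet(
        cifs={
            c: StepCurve(t_arr.copy(), np.array(out_cif[c]), initial=0.0)
            for c in causes
        },
        survival=StepCurve(t_arr.copy(), np.array(out_surv), initial=1.0),
    )
    result.check()
    return result
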