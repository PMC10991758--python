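"""Clone-censor-weight target-trial emulation.

Every patient is duplicated into both protocol arms ("treated within the
grace window" vs "not treated within the grace window"); a clone is
artificially censored on the day its source patient's actual treatment
deviates from its arm's strategy; selection induced by that censoring is
corrected with inverse-probability-of-censoring weights estimated within the
grace window; finally, per-arm weighted Aalen-Johansen cumulative incidence
curves and per-cause weighted Cox models (arm indicator as sole covariate,
robust variance clustered on the source patient) summarize the emulated
trial.  Confidence intervals come from a nonparametric patient-level
bootstrap (normal-based on the log-HR scale).

Cloning balances baseline covariates between arms exactly, removing baseline
confounding; keeping clones with events on or before their deviation day in
both arms removes immortal time by construction.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from .config import CAUSES
from .cox import CoxResults, CoxTimeVarying
from .data import analysis_design
from .nonparam import CIFSet, aalen_johansen, curve_at
from .weighting import _ipcw_core

__all__ = [
    "Protocol", "clone_and_censor", "TargetTrialEmulation",
    "EmulationResults", "emulate", "bootstrap_ci",
]

ARMS = ("control", "treated")
_CAUSE_CODE = {c: i for i, c in enumerate(CAUSES)}


@dataclass
class Protocol:
    """Emulated-trial protocol.

    ``grace`` is the number of days after admission within which initiation
    counts as following the treated strategy ("within 2 days" means
    treatment_day <= 2, admission being day 0).  With
    ``never_treat_control`` False (default), initiation *after* the grace
    window does not censor the control-arm clone: the control strategy
    constrains the grace window only.
    """

    grace: int = 2
    admin_end: int = 45
    n_boot: int = 500
    seed: int = 0
    never_treat_control: bool = False

    def validate(self) -> None:
        if not 0 < self.grace < self.admin_end:
            raise ValueError("grace must lie in (0, admin_end)")
        if self.n_boot <= 0:
            raise ValueError("n_boot must be positive")

    def to_yaml(self, path: str | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source: str) -> "Protocol":
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, ValueError):
            text = source
        proto = cls(**yaml.safe_load(text))
        proto.validate()
        return proto


# --------------------------------------------------------------------------
# cloning


def _clone_arrays(td, ed, cause_code, proto: Protocol):
    """Vectorized clone construction.

    Returns dict of arrays of length 2n (control arm first): ``arm`` (0/1),
    ``end``, ``cause`` (code, -1 = none), ``acens`` (artificial-censoring
    day, NaN if none) and ``src`` (source patient row index).
    """
    g = proto.grace
    n = len(ed)
    comply_by_grace = np.isfinite(td) & (td <= g)

    # treated arm: non-compliers deviate at end of grace
    t_end = np.where(comply_by_grace | (ed <= g), ed, g).astype(float)
    t_cause = np.where(comply_by_grace | (ed <= g), cause_code, -1)
    t_acens = np.where(comply_by_grace | (ed <= g), np.nan, float(g))

    # control arm: initiation within grace deviates on the initiation day
    dev = comply_by_grace & (ed > td)
    if proto.never_treat_control:
        late = np.isfinite(td) & (td > g) & (ed > td)
        dev = dev | late
    c_end = np.where(dev, td, ed).astype(float)
    c_cause = np.where(dev, -1, cause_code)
    c_acens = np.where(dev, td, np.nan)

    return {
        "arm": np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)]),
        "end": np.concatenate([c_end, t_end]),
        "cause": np.concatenate([c_cause, t_cause]).astype(int),
        "acens": np.concatenate([c_acens, t_acens]),
        "src": np.concatenate([np.arange(n), np.arange(n)]),
    }


def clone_and_censor(cohort: pd.DataFrame, protocol: Protocol) -> pd.DataFrame:
    """Two clones per patient with arm labels and artificial-censoring days.

    Clones whose source event occurred on or before their deviation day keep
    the event in both arms.
    """
    protocol.validate()
    ed = cohort["event_day"].to_numpy(dtype=float)
    if ed.max() > protocol.admin_end:
        raise ValueError("cohort follow-up exceeds protocol admin_end")
    td = cohort["treatment_day"].to_numpy(dtype=float)
    cause_code = np.array(
        [_CAUSE_CODE.get(c, -1) for c in cohort["event_type"]], dtype=int
    )
    arr = _clone_arrays(td, ed, cause_code, protocol)
    base = cohort.drop(columns=["event_day", "event_type"]).reset_index(drop=True)
    clones = pd.concat([base, base], ignore_index=True)
    clones["arm"] = np.where(arr["arm"] == 1, "treated", "control")
    clones["clone_end"] = arr["end"]
    code_to_name = {v: k for k, v in _CAUSE_CODE.items()}
    clones["clone_cause"] = [
        code_to_name.get(c, "none") for c in arr["cause"]
    ]
    clones["artificial_censor_day"] = arr["acens"]
    return clones


# --------------------------------------------------------------------------
# weighted interval rows


def _interval_rows(arr, weights_by_day, grace):
    """Expand clones into (start, stop] rows with piecewise-daily weights.

    The weight on interval (t, t+1] is the inverse probability of having
    remained artificially uncensored through day t (weight 1 on (0, 1]): the
    censoring factor for day s enters the weights only from day s+1 on, when
    the selection it corrects has actually acted on the risk set.
    """
    end = arr["end"]
    cause = arr["cause"]
    starts, stops, w, cse, arm, src = [], [], [], [], [], []
    for day in range(1, grace + 1):
        mask = end >= day
        starts.append(np.full(mask.sum(), day - 1.0))
        stops.append(np.full(mask.sum(), float(day)))
        w.append(
            np.ones(mask.sum()) if day == 1 else weights_by_day[mask, day - 2]
        )
        cse.append(np.where(end[mask] == day, cause[mask], -1))
        arm.append(arr["arm"][mask])
        src.append(arr["src"][mask])
    tail = end > grace
    starts.append(np.full(tail.sum(), float(grace)))
    stops.append(end[tail])
    w.append(weights_by_day[tail, grace - 1])
    cse.append(cause[tail])
    arm.append(arr["arm"][tail])
    src.append(arr["src"][tail])
    return {
        "start": np.concatenate(starts),
        "stop": np.concatenate(stops),
        "weight": np.concatenate(w),
        "cause": np.concatenate(cse),
        "arm": np.concatenate(arm),
        "src": np.concatenate(src),
    }


def _fit_arm_cox(rows, cause_code, ties="efron"):
    """Minimal-overhead weighted Cox with the arm indicator as covariate."""
    from .cox import _newton_1d_grid

    event = rows["cause"] == cause_code
    if not event.any():
        raise ValueError("no events of the requested cause")
    beta, var, converged = _newton_1d_grid(
        rows["start"], rows["stop"], event, rows["arm"].astype(float),
        rows["weight"], ties,
    )
    return beta, var, converged


# --------------------------------------------------------------------------
# results


@dataclass
class EmulationResults:
    """Outputs of the emulated trial analysis."""

    protocol: Protocol
    clones: pd.DataFrame
    weights: np.ndarray               # (n_clones, grace) cumulative weights
    arm_cifs: dict[str, CIFSet]
    cox_fits: dict[str, CoxResults]
    n_patients: int

    def hazard_ratio(self, cause: str = "death") -> tuple[float, float, float]:
        return self.cox_fits[cause].hazard_ratio("arm")

    def cif_at(self, cause: str, arm: str, t: float) -> float:
        cifs = self.arm_cifs[arm].cifs
        if cause not in cifs:  # no event of this cause observed in the arm
            return 0.0
        return float(curve_at(cifs[cause], t))

    def summary(self) -> pd.DataFrame:
        rows = []
        horizon = self.protocol.admin_end
        for cause in CAUSES:
            hr, lo, hi = self.hazard_ratio(cause)
            rows.append(
                {
                    "cause": cause,
                    "HR": hr, "CI_low": lo, "CI_high": hi,
                    "CIF_treated": self.cif_at(cause, "treated", horizon),
                    "CIF_control": self.cif_at(cause, "control", horizon),
                }
            )
        return pd.DataFrame(rows).set_index("cause")


class TargetTrialEmulation:
    """Clone-censor-weight analysis of one cohort under one protocol.

    Parameters
    ----------
    cohort : patient-level cohort frame (complete covariates).
    protocol : :class:`Protocol`.
    covariates : columns of the *transformed* design used in the censoring
        model; defaults to the standard analysis covariates.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        protocol: Protocol | None = None,
        covariates: list[str] | None = None,
    ):
        self.protocol = protocol or Protocol()
        self.protocol.validate()
        self.cohort = cohort.reset_index(drop=True)
        design = analysis_design(self.cohort)
        self.covariate_names = covariates or list(design.columns)
        self._design = design[self.covariate_names].to_numpy(dtype=float)
        self._td = self.cohort["treatment_day"].to_numpy(dtype=float)
        self._ed = self.cohort["event_day"].to_numpy(dtype=float)
        self._cause = np.array(
            [_CAUSE_CODE.get(c, -1) for c in self.cohort["event_type"]],
            dtype=int,
        )

    # internal array-level pipeline reused by the bootstrap
    def _run(self, idx=None, causes=CAUSES, with_cif=True, ties="efron"):
        td = self._td if idx is None else self._td[idx]
        ed = self._ed if idx is None else self._ed[idx]
        cc = self._cause if idx is None else self._cause[idx]
        X = self._design if idx is None else self._design[idx]
        arr = _clone_arrays(td, ed, cc, self.protocol)
        Xc = np.vstack([X, X])
        weights = _ipcw_core(
            arr["arm"], arr["end"], arr["acens"], Xc, self.protocol.grace
        )
        rows = _interval_rows(arr, weights, self.protocol.grace)
        fits = {}
        for cause in causes:
            fits[cause] = _fit_arm_cox(rows, _CAUSE_CODE[cause], ties)
        cifs = None
        if with_cif:
            cifs = {}
            code_to_name = {v: k for k, v in _CAUSE_CODE.items()}
            labels = np.array(
                [code_to_name.get(c, "none") for c in rows["cause"]],
                dtype=object,
            )
            for arm_code, arm in enumerate(ARMS):
                m = rows["arm"] == arm_code
                cifs[arm] = aalen_johansen(
                    rows["stop"][m], labels[m],
                    weights=rows["weight"][m], entry=rows["start"][m],
                )
        return arr, weights, rows, fits, cifs

    def fit(self, ties: str = "efron") -> EmulationResults:
        arr, weights, rows, _, cifs = self._run(ties=ties)
        clones = clone_and_censor(self.cohort, self.protocol)
        # full Cox fits (with cluster-robust variance) for reporting
        cox_fits = {}
        row_df = pd.DataFrame(
            {
                "start": rows["start"], "stop": rows["stop"],
                "weight": rows["weight"], "arm": rows["arm"].astype(float),
                "patient_id": rows["src"],
            }
        )
        for cause in CAUSES:
            row_df["event"] = (rows["cause"] == _CAUSE_CODE[cause]).astype(int)
            model = CoxTimeVarying(
                row_df, ["arm"], event_col="event", cluster_col="patient_id"
            )
            cox_fits[cause] = model.fit(ties=ties, robust=True)
        return EmulationResults(
            protocol=self.protocol,
            clones=clones,
            weights=weights,
            arm_cifs=cifs,
            cox_fits=cox_fits,
            n_patients=len(self.cohort),
        )

    # ---------------------------------------------------------------- boot
    def bootstrap(
        self,
        estimand: str = "log_hr:death",
        n_boot: int | None = None,
        seed: int | None = None,
    ) -> dict:
        """Patient-level nonparametric bootstrap of an emulation estimand.

        ``estimand`` is ``"log_hr:<cause>"`` (CI reported on the HR scale,
        normal-based on the log scale) or ``"cif_diff:<cause>:<day>"``
        (treated-minus-control CIF difference, normal-based on the
        probability scale).
        """
        n_boot = self.protocol.n_boot if n_boot is None else n_boot
        if n_boot < 2:
            raise ValueError("at least 2 bootstrap replicates required")
        seed = self.protocol.seed if seed is None else seed
        kind, _, rest = estimand.partition(":")
        if kind == "log_hr":
            cause, day = rest, None
        elif kind == "cif_diff":
            cause, _, day_s = rest.partition(":")
            day = float(day_s)
        else:
            raise ValueError(f"unknown estimand {estimand!r}")
        if cause not in CAUSES:
            raise ValueError(f"unknown cause {cause!r}")

        point = self._estimand_value(None, kind, cause, day)
        n = len(self.cohort)
        ss = np.random.SeedSequence(seed)
        streams = ss.spawn(n_boot)
        values = []
        failures = 0
        for st in streams:
            rng = np.random.default_rng(st)
            idx = rng.integers(0, n, size=n)
            try:
                values.append(self._estimand_value(idx, kind, cause, day))
            except (ValueError, np.linalg.LinAlgError):
                failures += 1
            if failures > 0.1 * n_boot:
                raise RuntimeError(
                    f"bootstrap fit failure rate exceeded 10% "
                    f"({failures}/{n_boot} so far)"
                )
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        lo, hi = point - 1.959963984540054 * sd, point + 1.959963984540054 * sd
        out = {
            "estimand": estimand,
            "replicates": len(values),
            "sd": sd,
        }
        if kind == "log_hr":
            out.update(
                estimate=float(np.exp(point)),
                log_estimate=point,
                ci_low=float(np.exp(lo)),
                ci_high=float(np.exp(hi)),
            )
        else:
            out.update(estimate=point, ci_low=lo, ci_high=hi)
        return out

    def _estimand_value(self, idx, kind, cause, day):
        if kind == "log_hr":
            _, _, _, fits, _ = self._run(idx, causes=(cause,), with_cif=False)
            beta, _, converged = fits[cause]
            if not converged or not np.isfinite(beta):
                raise ValueError("non-converged replicate")
            return beta
        _, _, _, _, cifs = self._run(idx, causes=(), with_cif=True)
        return float(
            curve_at(cifs["treated"].cifs[cause], day)
            - curve_at(cifs["control"].cifs[cause], day)
        )


def emulate(
    cohort: pd.DataFrame, protocol: Protocol | None = None
) -> EmulationResults:
    """One-call emulation: clone, censor, weight, estimate."""
    return TargetTrialEmulation(cohort, protocol).fit()


def bootstrap_ci(
    cohort: pd.DataFrame,
    protocol: Protocol | None = None,
    estimand: str = "log_hr:death",
    n_boot: int | None = None,
    seed: int | None = None,
) -> dict:
    """Nonparametric bootstrap CI for an emulation estimand."""
    return TargetTrialEmulation(cohort, protocol).bootstrap(
        estimand, n_boot=n_boot, seed=seed
    )
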