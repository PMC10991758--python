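"""Core cohort data model and analysis-view transformations.

A *cohort* is a pandas DataFrame with one row per patient and the columns of
:data:`COHORT_COLUMNS`; a *counting-process* frame has one row per (start,
stop] interval with a time-varying ``treated`` flag, the terminal ``cause``
on the final interval and an observation ``weight``.  The transformations
here build each analysis model's view of the data — including the
deliberately immortal-time-biased view in which ever-treated patients are
(incorrectly) classified as treated from admission.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CAUSES, MARKERS

COHORT_COLUMNS = [
    "patient_id", "age", "sex", "cci",
    "crp", "ldh", "ddimer", "lymph", "ferritin",
    "wave", "treatment_day", "event_day", "event_type",
]

EVENT_TYPES = (*CAUSES, "censored")

#: covariates entered into the regression models, after transformation
ANALYSIS_COVARIATES = [
    "age", "sex", "cci",
    "log_crp", "log_ldh", "log_ddimer", "sqrt_lymph", "log_ferritin",
    "wave2", "wave3",
]


def validate_cohort(cohort: pd.DataFrame, admin_end: int = 45) -> None:
    """Raise ValueError on schema or invariant violations."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort missing columns: {missing}")
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    ev = cohort["event_type"]
    bad = set(ev.unique()) - set(EVENT_TYPES)
    if bad:
        raise ValueError(f"unknown event types: {sorted(bad)}")
    day = cohort["event_day"]
    if (day < 1).any() or (day > admin_end).any():
        raise ValueError(f"event_day outside [1, {admin_end}]")
    if (day[ev == "censored"] != admin_end).any():
        raise ValueError("censored patients must have event_day == admin_end")
    td = cohort["treatment_day"]
    treated = td.notna()
    if (td[treated] > day[treated]).any():
        raise ValueError("treatment_day after event_day")
    if (td[treated] < 1).any():
        raise ValueError("treatment_day before day 1")
    for m in MARKERS:
        vals = cohort[m].dropna()
        if (vals <= 0).any():
            raise ValueError(f"non-positive values in marker {m!r}")


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write the canonical CSV (empty field = missing value)."""
    out = cohort[COHORT_COLUMNS].copy()
    out.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"event_type": str})
    for col in ("patient_id", "sex", "cci", "wave", "event_day"):
        df[col] = df[col].astype(np.int64)
    df["treatment_day"] = df["treatment_day"].astype(float)
    for m in MARKERS:
        df[m] = df[m].astype(float)
    return df[COHORT_COLUMNS]


# --------------------------------------------------------------------------
# counting-process views


def to_counting_process(cohort: pd.DataFrame) -> pd.DataFrame:
    """Start-stop representation with correctly time-varying treatment.

    Untreated patients contribute one interval (0, event_day]; a patient
    treated at day t < event_day contributes (0, t] untreated plus
    (t, event_day] treated.  A patient treated on the event day contributes a
    single untreated interval carrying the event: same-day initiation adds no
    treated person-time (treatment acts from the next day).
    """
    td = cohort["treatment_day"].to_numpy(dtype=float)
    day = cohort["event_day"].to_numpy(dtype=np.int64)
    if np.any(td[np.isfinite(td)] > day[np.isfinite(td)]):
        raise ValueError("treatment_day after event_day")
    split = np.isfinite(td) & (td < day)

    base = cohort.drop(columns=["treatment_day", "event_day", "event_type"])
    first = base.copy()
    first["start"] = 0
    first["stop"] = np.where(split, td, day).astype(np.int64)
    first["treated"] = 0
    first["cause"] = np.where(split, "none", cohort["event_type"])
    first.loc[first["cause"] == "censored", "cause"] = "none"

    second = base.loc[split].copy()
    second["start"] = td[split].astype(np.int64)
    second["stop"] = day[split]
    second["treated"] = 1
    cause2 = cohort.loc[split, "event_type"].to_numpy(dtype=object)
    cause2[cause2 == "censored"] = "none"
    second["cause"] = cause2

    rows = pd.concat([first, second], ignore_index=True)
    rows["weight"] = 1.0
    rows = rows.sort_values(["patient_id", "start"], kind="stable")
    return rows.reset_index(drop=True)


def misclassify_baseline(cohort: pd.DataFrame) -> pd.DataFrame:
    """The immortal-time-biased view: ever-treated patients misclassified as
    treated from admission (one interval (0, event_day] per patient)."""
    base = cohort.drop(columns=["treatment_day", "event_day", "event_type"])
    rows = base.copy()
    rows["start"] = 0
    rows["stop"] = cohort["event_day"].to_numpy(dtype=np.int64)
    rows["treated"] = cohort["treatment_day"].notna().astype(np.int64)
    cause = cohort["event_type"].to_numpy(dtype=object).copy()
    cause[cause == "censored"] = "none"
    rows["cause"] = cause
    rows["weight"] = 1.0
    return rows.reset_index(drop=True)


def cause_specific_view(rows: pd.DataFrame, cause: str) -> pd.DataFrame:
    """Binary-event view for one cause: other causes become censorings."""
    if cause not in CAUSES:
        raise ValueError(f"unknown cause {cause!r}")
    out = rows.copy()
    out["event"] = (rows["cause"] == cause).astype(np.int64)
    return out


# --------------------------------------------------------------------------
# covariate transforms


def analysis_design(cohort: pd.DataFrame) -> pd.DataFrame:
    """Transformed baseline covariates used by the regression models.

    Log transform for CRP, LDH, D-dimer and ferritin; square root for the
    lymphocyte count; pandemic wave as indicator contrasts against wave 1.
    Raises if any marker value is missing (impute first).
    """
    labs = cohort[list(MARKERS)]
    if labs.isna().any().any():
        raise ValueError(
            "missing inflammatory-marker values: run multiple imputation first"
        )
    out = pd.DataFrame(index=cohort.index)
    out["age"] = cohort["age"].astype(float)
    out["sex"] = cohort["sex"].astype(float)
    out["cci"] = cohort["cci"].astype(float)
    out["log_crp"] = np.log(cohort["crp"].astype(float))
    out["log_ldh"] = np.log(cohort["ldh"].astype(float))
    out["log_ddimer"] = np.log(cohort["ddimer"].astype(float))
    out["sqrt_lymph"] = np.sqrt(cohort["lymph"].astype(float))
    out["log_ferritin"] = np.log(cohort["ferritin"].astype(float))
    out["wave2"] = (cohort["wave"] == 2).astype(float)
    out["wave3"] = (cohort["wave"] == 3).astype(float)
    return out


def attach_design(rows: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Merge analysis covariates onto counting-process rows by patient_id."""
    design = analysis_design(cohort)
    design = design.set_index(cohort["patient_id"])
    merged = rows.join(design, on="patient_id", rsuffix="_x")
    return merged


# --------------------------------------------------------------------------
# summaries


def event_table(cohort: pd.DataFrame, grace: int = 2) -> pd.DataFrame:
    """Counts and fractions of each event type plus treatment uptake."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    n = len(cohort)
    rows = []
    for ev in EVENT_TYPES:
        k = int((cohort["event_type"] == ev).sum())
        rows.append((ev, k, k / n))
    k_ever = int(cohort["treatment_day"].notna().sum())
    k_grace = int((cohort["treatment_day"] <= grace).sum())
    disch = cohort["event_type"].isin(["home", "transfer"])
    n_disch = int(disch.sum())
    k_home = int((cohort.loc[disch, "event_type"] == "home").sum())
    rows.append(("discharged", n_disch, n_disch / n))
    rows.append(
        ("home_among_discharged", k_home, k_home / n_disch if n_disch else np.nan)
    )
    rows.append(("ever_treated", k_ever, k_ever / n))
    rows.append((f"treated_by_day_{grace}", k_grace, k_grace / n))
    return pd.DataFrame(rows, columns=["quantity", "count", "fraction"])
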