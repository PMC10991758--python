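"""Configuration of the synthetic hospital-cohort generator.

The generator simulates a cohort of hospitalized patients followed for
``admin_end`` days after admission (day 0).  Each day an untreated patient may
initiate a single-dose treatment, and every in-hospital patient may experience
one of three competing terminal events — in-hospital death, discharge home, or
transfer to another healthcare facility — driven by cause-specific daily
hazards that depend on baseline covariates and on current treatment status.
Patients still in hospital at ``admin_end`` are administratively censored.

All covariate effects are expressed on internally standardized scales (see
:meth:`GeneratorConfig.standardizers`), so intercepts control marginal event
frequencies and coefficients control confounding strength independently.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

SCHEMA_VERSION = 1

CAUSES = ("death", "home", "transfer")
MARKERS = ("crp", "ldh", "ddimer", "lymph", "ferritin")

#: covariate names usable in hazard / treatment linear predictors
LP_COVARIATES = (
    "age",
    "sex",
    "cci",
    "crp",
    "ldh",
    "ddimer",
    "lymph",
    "ferritin",
    "wave2",
    "wave3",
)


@dataclass
class LabParams:
    """Log-scale location/dispersion of one inflammatory marker.

    ``value = exp(mu + loading * Z + sigma * eps)`` with a shared latent
    severity factor ``Z`` and independent noise ``eps`` (both standard normal).
    A negative loading encodes markers that are *low* in severe disease
    (lymphocyte count).
    """

    mu: float
    loading: float
    sigma: float

    @property
    def total_sd(self) -> float:
        return math.sqrt(self.loading**2 + self.sigma**2)


def _default_labs() -> dict[str, LabParams]:
    # Locations chosen so that the clinical high-risk thresholds
    # (CRP>102 mg/L, LDH>394 U/L, D-dimer>1580 ng/mL, lymphocytes<760e6/L,
    # ferritin>1360 mcg/L) sit near the outer quintile of each marker.
    return {
        "crp": LabParams(mu=math.log(60.0), loading=0.50, sigma=0.62),
        "ldh": LabParams(mu=math.log(300.0), loading=0.22, sigma=0.22),
        "ddimer": LabParams(mu=math.log(700.0), loading=0.60, sigma=0.80),
        "lymph": LabParams(mu=math.log(1100.0), loading=-0.45, sigma=0.50),
        "ferritin": LabParams(mu=math.log(600.0), loading=0.55, sigma=0.75),
    }


def _zero_coefs() -> dict[str, float]:
    return {name: 0.0 for name in LP_COVARIATES}


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort generator."""

    n: int = 478
    seed: int = 0
    admin_end: int = 45
    grace_ref: int = 2

    # --- baseline covariates -------------------------------------------------
    age_mean: float = 66.0
    age_sd: float = 13.0
    age_min: float = 18.0
    age_max: float = 100.0
    male_prop: float = 0.62
    wave_probs: tuple[float, float, float] = (0.45, 0.30, 0.25)
    cci_log_mean: float = 0.33
    cci_age_coef: float = 0.20      # per SD of age, on log(mean CCI)
    cci_severity_coef: float = 0.20  # per SD of latent severity
    cci_max: int = 12
    labs: dict[str, LabParams] = field(default_factory=_default_labs)

    # --- cause-specific event process ---------------------------------------
    #: log daily hazard rate at covariate means, untreated
    base_log_hazard: dict[str, float] = field(
        default_factory=lambda: {"death": -3.90, "home": -4.17, "transfer": -4.52}
    )
    #: per-cause covariate log-hazard coefficients (standardized covariates)
    cause_coefs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: _zero_coefs() for c in CAUSES}
    )
    #: true treatment log hazard ratios, acting from the day after initiation
    treat_log_hr: dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in CAUSES}
    )

    # --- treatment-initiation process ---------------------------------------
    #: logit daily initiation probability on days 1..grace_ref / afterwards
    treat_logit_early: float = -2.44
    treat_logit_late: float = -4.38
    treat_coefs: dict[str, float] = field(default_factory=_zero_coefs)

    # --- missingness in inflammatory markers --------------------------------
    missing_rates: dict[str, float] = field(
        default_factory=lambda: {m: 0.0 for m in MARKERS}
    )
    missing_mechanism: str = "MAR"  # or "MCAR"
    mar_age_coef: float = 0.5       # logit missingness per SD of age
    mar_wave1_coef: float = 0.6     # extra logit missingness in wave 1

    schema_version: int = SCHEMA_VERSION

    # ------------------------------------------------------------------ utils
    def standardizers(self) -> dict[str, tuple[float, float]]:
        """(center, scale) used for each linear-predictor covariate.

        Lab markers are standardized on the log scale using the analytic mean
        and SD implied by their parameters, so linear predictors are exactly
        mean-zero in expectation.
        """
        std = {
            "age": (self.age_mean, self.age_sd),
            "sex": (self.male_prop, 1.0),
            "cci": (1.5, 1.5),
            "wave2": (self.wave_probs[1], 1.0),
            "wave3": (self.wave_probs[2], 1.0),
        }
        for m, p in self.labs.items():
            std[m] = (p.mu, p.total_sd)
        return std

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.admin_end <= 0:
            raise ValueError("admin_end must be positive")
        if not 0 < self.grace_ref < self.admin_end:
            raise ValueError("grace_ref must lie in (0, admin_end)")
        if abs(sum(self.wave_probs) - 1.0) > 1e-9 or min(self.wave_probs) < 0:
            raise ValueError("wave_probs must be non-negative and sum to 1")
        if not 0.0 <= self.male_prop <= 1.0:
            raise ValueError("male_prop must be in [0, 1]")
        for cause in CAUSES:
            if cause not in self.base_log_hazard:
                raise ValueError(f"missing base hazard for cause {cause!r}")
            # daily event probability is 1 - exp(-sum of rates), so any finite
            # log-rate keeps probabilities inside [0, 1]
            if not math.isfinite(self.base_log_hazard[cause]):
                raise ValueError(f"non-finite baseline hazard for {cause!r}")
        for m, r in self.missing_rates.items():
            if m not in MARKERS:
                raise ValueError(f"unknown marker {m!r}")
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missing rate for {m!r} outside [0, 1]")
        if self.missing_mechanism not in ("MAR", "MCAR"):
            raise ValueError("missing_mechanism must be 'MAR' or 'MCAR'")
        for coefs in (*self.cause_coefs.values(), self.treat_coefs):
            for k, v in coefs.items():
                if k not in LP_COVARIATES:
                    raise ValueError(f"unknown covariate {k!r} in coefficients")
                if not math.isfinite(v):
                    raise ValueError(f"non-finite coefficient for {k!r}")

    def replace(self, **changes: Any) -> "GeneratorConfig":
        """Return a deep-copied config with the given fields replaced."""
        d = self.to_dict()
        d.update(_serialize(changes))
        return GeneratorConfig.from_dict(d)

    # -------------------------------------------------------------- serialize
    def to_dict(self) -> dict[str, Any]:
        return _serialize(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GeneratorConfig":
        d = dict(d)
        version = d.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        if "labs" in d:
            d["labs"] = {
                k: v if isinstance(v, LabParams) else LabParams(**v)
                for k, v in d["labs"].items()
            }
        if "wave_probs" in d:
            d["wave_probs"] = tuple(d["wave_probs"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source: str) -> "GeneratorConfig":
        """Load from a YAML string or a path to a YAML file."""
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, ValueError):
            text = source
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        return cls.from_dict(json.loads(text))


def _serialize(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _serialize(v) for k, v in obj.items()}
    if isinstance(obj, LabParams):
        return dataclasses.asdict(obj)
    if isinstance(obj, tuple):
        return [_serialize(v) for v in obj]
    if isinstance(obj, list):
        return [_serialize(v) for v in obj]
    return obj
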