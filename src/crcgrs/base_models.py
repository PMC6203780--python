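"""Published-style colorectal-cancer risk models.

Two model shapes are supported:

* an *age-rate x family-history* absolute-risk model: age-specific
  incidence rates are integrated over the prediction horizon and scaled by
  a family-history relative risk, so the absolute risk is
  ``1 - exp(-RR_fh * integral of lambda_0(a) da)``;
* a *Cox-coefficient* model: a linear predictor ``eta = sum beta_k
  f_k(x_k)`` over lifestyle covariates plus a 5-year baseline survival
  ``S0``, giving ``risk = 1 - S0 ** exp(eta)``.

Both produce a log relative hazard (used as the recalibration covariate)
and a 5-year absolute risk.  No competing-mortality adjustment is applied.
Coefficients and codings live in external model-spec files; the tables
shipped with the package are synthetic fixtures, not published values.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AgeRateTable",
    "FamilyHistoryRR",
    "CoxCovariate",
    "CoxModelSpec",
    "RiskPrediction",
    "taylor_absolute_risk",
    "cox_linear_predictor",
    "cox_absolute_risk",
    "remove_covariate_effect",
]


@dataclass
class RiskPrediction:
    """Per-participant log relative hazard and absolute risk."""

    log_hazard_ratio: np.ndarray
    risk: np.ndarray

    def __post_init__(self):
        self.log_hazard_ratio = np.atleast_1d(np.asarray(self.log_hazard_ratio, float))
        self.risk = np.atleast_1d(np.asarray(self.risk, float))
        if np.any((self.risk < 0) | (self.risk > 1)):
            raise ValueError("absolute risks must lie in [0, 1]")


class AgeRateTable:
    """Piecewise-constant incidence rates over half-open age bands [lo, hi)."""

    def __init__(self, table: pd.DataFrame):
        required = {"age_lower", "age_upper", "rate"}
        if not required <= set(table.columns):
            raise ValueError(f"rate table needs columns {sorted(required)}")
        t = table.sort_values("age_lower").reset_index(drop=True)
        lo = t["age_lower"].to_numpy(float)
        hi = t["age_upper"].to_numpy(float)
        r = t["rate"].to_numpy(float)
        if np.any(hi <= lo):
            raise ValueError("age bands must have upper > lower")
        if np.any(r < 0):
            raise ValueError("rates must be non-negative")
        if np.any(lo[1:] != hi[:-1]):
            raise ValueError("age bands must be contiguous and non-overlapping")
        self.lower, self.upper, self.rate = lo, hi, r

    @classmethod
    def from_tsv(cls, path) -> "AgeRateTable":
        return cls(pd.read_csv(path, sep="\t"))

    def cumulative_hazard(self, age_start: float, age_end: float) -> float:
        """Exact integral of the piecewise-constant rate over [age_start, age_end)."""
        if age_end < age_start:
            raise ValueError("age_end must be >= age_start")
        if age_start < self.lower[0] or age_end > self.upper[-1]:
            raise ValueError(
                f"age range [{age_start}, {age_end}) not covered by rate table "
                f"[{self.lower[0]}, {self.upper[-1]})"
            )
        overlap = np.clip(
            np.minimum(age_end, self.upper) - np.maximum(age_start, self.lower),
            0.0,
            None,
        )
        return float(np.sum(overlap * self.rate))


class FamilyHistoryRR:
    """Relative risks by family-history category; the reference has RR = 1."""

    def __init__(self, rr: dict):
        if not rr:
            raise ValueError("empty relative-risk map")
        if any(v <= 0 for v in rr.values()):
            raise ValueError("relative risks must be positive")
        if not any(np.isclose(v, 1.0) for v in rr.values()):
            raise ValueError("one category must be the reference with RR = 1")
        self.rr = {k: float(v) for k, v in rr.items()}

    @classmethod
    def from_tsv(cls, path) -> "FamilyHistoryRR":
        t = pd.read_csv(path, sep="\t")
        return cls(dict(zip(t["fh_category"], t["relative_risk"])))

    def __getitem__(self, category) -> float:
        if category not in self.rr:
            raise KeyError(f"family-history category {category!r} not in RR table")
        return self.rr[category]


def taylor_absolute_risk(
    age,
    fh_category,
    rates: AgeRateTable,
    rr: FamilyHistoryRR,
    horizon: float = 5.0,
) -> RiskPrediction:
    """Absolute risk from age-specific rates scaled by a family-history RR.

    Cumulative hazard over [age, age + horizon):
    ``Lambda = RR_fh * sum_bands rate * overlap``; risk is
    ``1 - exp(-Lambda)`` and the log relative hazard is ``log RR_fh``.
    Accepts scalars or aligned vectors.
    """
    ages = np.atleast_1d(np.asarray(age, float))
    cats = np.atleast_1d(np.asarray(fh_category))
    if cats.shape != ages.shape:
        raise ValueError("age and family-history vectors must be aligned")
    lam0 = np.array([rates.cumulative_hazard(a, a + horizon) for a in ages])
    rrs = np.array([rr[c] for c in cats])
    risk = 1.0 - np.exp(-rrs * lam0)
    return RiskPrediction(log_hazard_ratio=np.log(rrs), risk=risk)


@dataclass
class CoxCovariate:
    """One term of a Cox-style linear predictor.

    ``kind = "linear"`` contributes ``coef * (x - reference) / per_unit``;
    ``kind = "categorical"`` contributes ``levels[x]`` (log HR per level,
    reference level 0).  ``sex_mask`` restricts the term to one sex ("F" or
    "M"); non-applicable participants contribute exactly 0.
    """

    name: str
    coef: float = 0.0
    kind: str = "linear"
    reference: float = 0.0
    per_unit: float = 1.0
    levels: dict = field(default_factory=dict)
    sex_mask: str | None = None

    def contribution(self, values: pd.Series, sex: pd.Series | None) -> np.ndarray:
        if self.kind == "linear":
            term = self.coef * (values.to_numpy(float) - self.reference) / self.per_unit
        elif self.kind == "categorical":
            unknown = set(values.unique()) - set(self.levels)
            if unknown:
                raise ValueError(
                    f"covariate {self.name}: levels {sorted(map(str, unknown))} "
                    "not in model spec"
                )
            term = values.map(self.levels).to_numpy(float)
        else:
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.sex_mask is not None:
            if sex is None:
                raise ValueError(
                    f"covariate {self.name} is sex-restricted but no sex column given"
                )
            term = np.where(sex.to_numpy() == self.sex_mask, term, 0.0)
        return term


@dataclass
class CoxModelSpec:
    """A published Cox model: coefficients plus 5-year baseline survival."""

    covariates: list[CoxCovariate]
    baseline_survival: float  # S0(horizon) at the covariate reference
    horizon: float = 5.0
    name: str = "cox-model"

    def __post_init__(self):
        if not 0.0 < self.baseline_survival <= 1.0:
            raise ValueError("baseline survival must lie in (0, 1]")
        for c in self.covariates:
            if not np.isfinite(c.coef):
                raise ValueError(f"non-finite coefficient for {c.name}")

    @property
    def covariate_names(self) -> list[str]:
        return [c.name for c in self.covariates]

    @classmethod
    def from_yaml(cls, path) -> "CoxModelSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        covs = [CoxCovariate(**c) for c in raw["covariates"]]
        return cls(
            covariates=covs,
            baseline_survival=float(raw["baseline_survival"]),
            horizon=float(raw.get("horizon", 5.0)),
            name=str(raw.get("name", "cox-model")),
        )


def cox_linear_predictor(covariates: pd.DataFrame, spec: CoxModelSpec) -> np.ndarray:
    """eta = sum_k beta_k * transform_k(x_k) over the spec's covariates."""
    missing = [c.name for c in spec.covariates if c.name not in covariates.columns]
    if missing:
        raise ValueError(f"missing required covariates: {missing}")
    sex = covariates["sex"] if "sex" in covariates.columns else None
    eta = np.zeros(len(covariates))
    for cov in spec.covariates:
        eta += cov.contribution(covariates[cov.name], sex)
    return eta


def cox_absolute_risk(
    eta: np.ndarray, spec: CoxModelSpec, horizon: float | None = None
) -> RiskPrediction:
    """risk = 1 - S0(horizon) ** exp(eta)."""
    if horizon is not None and not np.isclose(horizon, spec.horizon):
        raise ValueError(
            f"spec provides S0 at {spec.horizon} years, not {horizon}"
        )
    eta = np.atleast_1d(np.asarray(eta, float))
    risk = 1.0 - spec.baseline_survival ** np.exp(eta)
    return RiskPrediction(log_hazard_ratio=eta, risk=risk)


def remove_covariate_effect(spec, names):
    """Return a copy of a model with the named coefficients zeroed.

    For a Cox spec, both linear coefficients and categorical level log HRs
    of the named covariates are set to 0.  For a family-history RR model,
    passing ``names=["age"]`` is meaningless; use the Cox path.  The input
    is never modified.
    """
    names = list(names)
    out = copy.deepcopy(spec)
    known = {c.name for c in out.covariates}
    unknown = [n for n in names if n not in known]
    if unknown:
        raise ValueError(f"unknown covariates: {unknown}")
    for cov in out.covariates:
        if cov.name in names:
            cov.coef = 0.0
            cov.levels = {k: 0.0 for k in cov.levels}
    return out
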