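"""Recalibration of published risk models, with and without the GRS.

Two stages mirror how an external model is brought onto a new cohort:

1. *Initial calibration* fits a flexible parametric survival model with
   the published model's log hazard ratio as an offset (coefficient fixed
   at 1), re-estimating only the baseline spline — calibration-in-the-
   large.  A slope-estimation mode that frees the coefficient is also
   available.
2. *GRS-augmented recalibration* fits the base log HR and the
   (mean-centred) GRS as separate free covariates; the fitted
   coefficients are calibration slopes.  A slope of 1 on the base log HR
   means the published relative risks hold in the cohort; a slope below 1
   on the GRS is the signature of winner's-curse-inflated weights.

Per-participant change in predicted 5-year risk between the base-only and
augmented recalibrated models is summarised by the proportion whose risk
moves by at least a threshold (default 0.3 percentage points), overall and
among participants whose initial risk is at least a high-risk cutoff
(default 1%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fpsm import FPSMFit, fit_fpsm, predict_risk

__all__ = [
    "RecalibrationResult",
    "DeltaRiskSummary",
    "initial_calibration",
    "recalibrate_with_grs",
    "delta_risk_summary",
]


def initial_calibration(
    base_log_hr,
    time,
    event,
    df: int = 2,
    mode: str = "offset",
) -> FPSMFit:
    """Calibrate a published model's baseline to the target cohort.

    ``mode="offset"`` (default) keeps the published relative risks fixed
    (coefficient 1) and re-estimates the baseline spline only;
    ``mode="slope"`` additionally estimates a calibration slope on the
    published log hazard ratio.
    """
    eta = np.asarray(base_log_hr, float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("base-model log hazard ratios must be finite")
    if mode == "offset":
        return fit_fpsm(time, event, covariates=None, df=df, offset=eta)
    if mode == "slope":
        return fit_fpsm(
            time, event, covariates=eta[:, None], df=df,
            covariate_names=("base_log_hr",),
        )
    raise ValueError(f"unknown calibration mode {mode!r}")


@dataclass
class RecalibrationResult:
    """Base-only and GRS-augmented recalibrated models on one cohort."""

    fit_base: FPSMFit
    fit_augmented: FPSMFit
    risks_base: np.ndarray
    risks_augmented: np.ndarray
    slope_base: float
    slope_base_se: float
    slope_grs: float
    slope_grs_se: float
    horizon: float

    def grs_slope_ci(self, conf_level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + conf_level / 2.0)
        return (
            self.slope_grs - z * self.slope_grs_se,
            self.slope_grs + z * self.slope_grs_se,
        )

    def summary(self) -> dict:
        lo, hi = self.grs_slope_ci()
        return {
            "slope_base": self.slope_base,
            "slope_base_se": self.slope_base_se,
            "slope_grs": self.slope_grs,
            "slope_grs_se": self.slope_grs_se,
            "slope_grs_ci": [lo, hi],
            "horizon": self.horizon,
            "loglik_base": self.fit_base.loglik,
            "loglik_augmented": self.fit_augmented.loglik,
        }


def recalibrate_with_grs(
    base_log_hr,
    grs,
    time,
    event,
    df: int = 2,
    horizon: float = 5.0,
) -> RecalibrationResult:
    """Fit base-only and GRS-augmented recalibration models.

    Both fits share the same knot specification (placed by the base-only
    fit) so their predicted risks are directly comparable.  Returns the
    two fits, per-participant risks at ``horizon`` years, and the
    calibration slopes with standard errors.
    """
    eta = np.asarray(base_log_hr, float)
    g = np.asarray(grs, float)
    time = np.asarray(time, float)
    event = np.asarray(event)
    if not eta.shape == g.shape == time.shape == event.shape:
        raise ValueError("input vectors must be aligned")
    if not np.all(np.isfinite(eta)) or not np.all(np.isfinite(g)):
        raise ValueError("covariates must be finite")
    if np.ptp(eta) > 0 and np.ptp(g) > 0:
        r = np.corrcoef(eta, g)[0, 1]
        if abs(r) > 0.999:
            raise ValueError(
                f"base log HR and GRS are collinear (|corr| = {abs(r):.4f})"
            )
    fit_base = fit_fpsm(
        time, event, covariates=eta[:, None], df=df,
        covariate_names=("base_log_hr",),
    )
    grs_varies = np.ptp(g) > 0
    if grs_varies:
        fit_aug = fit_fpsm(
            time, event, covariates=np.column_stack([eta, g]), df=df,
            knots=fit_base.basis,
            covariate_names=("base_log_hr", "grs"),
        )
        slope_grs = float(fit_aug.beta[1])
        slope_grs_se = float(fit_aug.beta_se[1])
        risks_aug = predict_risk(fit_aug, np.column_stack([eta, g]), horizon)
    else:
        # degenerate GRS carries no information; augmented model == base model
        fit_aug = fit_base
        slope_grs, slope_grs_se = 0.0, float("nan")
        risks_aug = predict_risk(fit_base, eta[:, None], horizon)
    risks_base = predict_risk(fit_base, eta[:, None], horizon)
    return RecalibrationResult(
        fit_base=fit_base,
        fit_augmented=fit_aug,
        risks_base=risks_base,
        risks_augmented=risks_aug,
        slope_base=float(fit_base.beta[0]),
        slope_base_se=float(fit_base.beta_se[0]),
        slope_grs=slope_grs,
        slope_grs_se=slope_grs_se,
        horizon=horizon,
    )


@dataclass
class DeltaRiskSummary:
    """How much predicted risks move when the GRS is added."""

    threshold: float
    high_risk_cutoff: float
    n: int
    n_high_risk: int
    prop_exceeding: float
    prop_exceeding_high_risk: float
    deltas: np.ndarray

    def summary(self) -> dict:
        return {
            "threshold": self.threshold,
            "high_risk_cutoff": self.high_risk_cutoff,
            "n": self.n,
            "n_high_risk": self.n_high_risk,
            "prop_exceeding": self.prop_exceeding,
            "prop_exceeding_high_risk": self.prop_exceeding_high_risk,
        }


def delta_risk_summary(
    risks_base,
    risks_augmented,
    threshold: float = 0.003,
    high_risk_cutoff: float = 0.01,
) -> DeltaRiskSummary:
    """Proportion of participants whose predicted risk changes by at least
    ``threshold`` (absolute probability points, tie rule ">="), overall and
    among those with base risk at or above ``high_risk_cutoff``."""
    rb = np.asarray(risks_base, float)
    ra = np.asarray(risks_augmented, float)
    if rb.shape != ra.shape:
        raise ValueError("risk vectors must be aligned")
    if not 0.0 <= threshold < 1.0 or not 0.0 < high_risk_cutoff < 1.0:
        raise ValueError("threshold and cutoff must be probabilities")
    delta = ra - rb
    exceed = np.abs(delta) >= threshold
    high = rb >= high_risk_cutoff
    return DeltaRiskSummary(
        threshold=threshold,
        high_risk_cutoff=high_risk_cutoff,
        n=rb.size,
        n_high_risk=int(high.sum()),
        prop_exceeding=float(exceed.mean()) if rb.size else 0.0,
        prop_exceeding_high_risk=float(exceed[high].mean()) if high.any() else 0.0,
        deltas=delta,
    )
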