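"""Calibration and discrimination assessment for censored risk predictions.

Discrimination uses Harrell's C over censoring-comparable pairs; absolute
calibration compares mean predicted probability with the Kaplan–Meier
observed probability by tenths of predicted risk; relative-risk
calibration plots the hazard ratio estimated by a flexible parametric
survival model against the model-predicted hazard ratio (the identity line
is perfect calibration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fpsm import SplineBasisSpec, fit_fpsm, rcs_basis

__all__ = [
    "ConcordanceResult",
    "RRCalibrationCurve",
    "km_estimator",
    "harrell_c",
    "calibration_by_tenths",
    "rr_calibration",
]


def km_estimator(time, event, t: float, conf_level: float = 0.95):
    """Kaplan–Meier event probability 1 - S(t) with a Greenwood CI.

    The CI is computed on the log(-log S) scale and back-transformed, the
    standard transform that keeps the bounds inside [0, 1].  Returns
    ``(estimate, lower, upper)`` as event probabilities.
    """
    time = np.asarray(time, float)
    event = np.asarray(event)
    if time.size == 0:
        raise ValueError("no observations")
    if t <= 0:
        raise ValueError("t must be positive")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    # distinct event times up to t with deaths and numbers at risk
    s = 1.0
    greenwood = 0.0
    n_at_risk = time.size
    i = 0
    n = time.size
    while i < n and time[i] <= t:
        ti = time[i]
        d = 0
        c = 0
        while i < n and time[i] == ti:
            if event[i]:
                d += 1
            else:
                c += 1
            i += 1
        if d > 0:
            s *= 1.0 - d / n_at_risk
            if n_at_risk > d:
                greenwood += d / (n_at_risk * (n_at_risk - d))
            else:
                greenwood = np.inf
        n_at_risk -= d + c
    est = 1.0 - s
    if s <= 0.0 or s >= 1.0 or not np.isfinite(greenwood):
        return est, (0.0 if s >= 1.0 else est), (est if s <= 0.0 else 1.0)
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    se_cloglog = np.sqrt(greenwood) / abs(np.log(s))
    s_lo = s ** np.exp(z * se_cloglog)
    s_hi = s ** np.exp(-z * se_cloglog)
    return est, 1.0 - s_hi, 1.0 - s_lo


@dataclass
class ConcordanceResult:
    """Harrell's C with an asymptotic (U-statistic) confidence interval."""

    c_statistic: float
    ci_lower: float
    ci_upper: float
    n_comparable: int
    n_concordant: float
    n_tied_score: int

    def __iter__(self):  # convenient (c, lo, hi) unpacking
        return iter((self.c_statistic, self.ci_lower, self.ci_upper))


def harrell_c(time, event, score, conf_level: float = 0.95) -> ConcordanceResult:
    """Harrell's concordance for right-censored data.

    A pair is comparable when the member with the earlier time had an
    event (or, at tied times, exactly one member had an event).  Credit is
    1 for the shorter-lived member having the higher score, 0.5 for tied
    scores.  The CI uses the asymptotic variance of the two-sample
    U-statistic via per-subject influence terms.
    """
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    score = np.asarray(score, float)
    if not time.shape == event.shape == score.shape:
        raise ValueError("time, event and score must be aligned")
    n = time.size
    conc = np.zeros(n)  # concordance credit per subject
    comp = np.zeros(n)  # comparable pairs per subject
    ev_idx = np.flatnonzero(event)
    if ev_idx.size == 0:
        raise ValueError("no comparable pairs: no events")
    n_tied = 0
    for i in ev_idx:
        # later times always comparable; tied times comparable iff censored
        later = time > time[i]
        tied_t = (time == time[i]) & ~event
        mask = later | tied_t
        mask[i] = False
        if not mask.any():
            continue
        sj = score[mask]
        credit = np.where(sj < score[i], 1.0, np.where(sj == score[i], 0.5, 0.0))
        n_tied += int((sj == score[i]).sum())
        conc[i] += credit.sum()
        comp[i] += credit.size
        np.add.at(conc, np.flatnonzero(mask), credit)
        np.add.at(comp, np.flatnonzero(mask), 1.0)
    total_comp = comp.sum() / 2.0
    if total_comp == 0:
        raise ValueError("no comparable pairs")
    total_conc = conc.sum() / 2.0
    c = total_conc / total_comp
    # influence-function variance for the ratio of two degree-2 U-statistics
    mean_comp = comp.mean()
    psi = (conc - c * comp) / mean_comp
    var = float(np.sum(psi**2)) / n**2 * 4.0
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    half = z * np.sqrt(var)
    return ConcordanceResult(
        c_statistic=float(c),
        ci_lower=max(0.0, float(c - half)),
        ci_upper=min(1.0, float(c + half)),
        n_comparable=int(round(total_comp)),
        n_concordant=float(total_conc),
        n_tied_score=n_tied,
    )


def calibration_by_tenths(predicted, time, event, horizon: float) -> pd.DataFrame:
    """Observed (Kaplan–Meier) vs mean predicted risk by tenths of risk.

    Participants are ranked by predicted risk (ties broken by stable input
    order) and split into 10 groups whose sizes differ by at most one.
    Returns one row per group: n, mean predicted, KM observed at the
    horizon with its CI.
    """
    predicted = np.asarray(predicted, float)
    time = np.asarray(time, float)
    event = np.asarray(event)
    if np.any((predicted < 0) | (predicted > 1)):
        raise ValueError("predicted risks must lie in [0, 1]")
    n = predicted.size
    if n < 10:
        raise ValueError("need at least 10 participants for tenths")
    order = np.argsort(predicted, kind="stable")
    groups = np.array_split(order, 10)
    rows = []
    for g, idx in enumerate(groups, start=1):
        obs, lo, hi = km_estimator(time[idx], event[idx], horizon)
        rows.append(
            {
                "group": g,
                "n": idx.size,
                "mean_predicted": float(predicted[idx].mean()),
                "km_observed": obs,
                "km_lower": lo,
                "km_upper": hi,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RRCalibrationCurve:
    """Estimated vs model-predicted hazard ratios on a grid.

    ``reference_log_hr`` is the cohort-mean predicted log HR; both axes
    equal 1 there by construction.  Perfect relative-risk calibration puts
    the curve on the identity; a flatter curve means the model's relative
    risks are more extreme than those observed.
    """

    predicted_hr: np.ndarray
    estimated_hr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    reference_log_hr: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predicted_hr": self.predicted_hr,
                "estimated_hr": self.estimated_hr,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


def rr_calibration(
    pred_log_hr,
    time,
    event,
    df_curve: int = 2,
    df_baseline: int = 2,
    n_grid: int = 41,
    conf_level: float = 0.95,
) -> RRCalibrationCurve:
    """Relative-risk calibration curve from a flexible parametric fit.

    The predicted log HR enters the model through a restricted cubic
    spline with ``df_curve`` terms, so the estimated HR may bend away from
    the identity wherever the data demand it.  HRs are expressed relative
    to the cohort-mean predicted log HR.
    """
    x = np.asarray(pred_log_hr, float)
    if not np.all(np.isfinite(x)):
        raise ValueError("predicted log hazard ratios must be finite")
    if np.ptp(x) <= 0:
        raise ValueError("predicted log hazard ratios have no variation")
    if df_curve == 1:
        spec = None
        X = x[:, None]
    else:
        lo, hi = float(x.min()), float(x.max())
        probs = np.linspace(0.0, 1.0, df_curve + 1)[1:-1]
        interior = tuple(float(q) for q in np.quantile(x, probs))
        spec = SplineBasisSpec(df=df_curve, boundary_knots=(lo, hi), interior_knots=interior)
        X = rcs_basis(x, spec)
    fit = fit_fpsm(time, event, covariates=X, df=df_baseline)
    ref = float(x.mean())
    grid = np.linspace(x.min(), x.max(), n_grid)
    Bg = grid[:, None] if spec is None else rcs_basis(grid, spec)
    Br = np.atleast_2d(ref) if spec is None else rcs_basis(np.array([ref]), spec)
    D = Bg - Br  # contrast vs the reference point
    log_hr = D @ fit.beta
    k = len(fit.gamma)
    cov_beta = fit.covariance[k:, k:]
    se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", D, cov_beta, D), 0.0, None))
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    return RRCalibrationCurve(
        predicted_hr=np.exp(grid - ref),
        estimated_hr=np.exp(log_hr),
        ci_lower=np.exp(log_hr - z * se),
        ci_upper=np.exp(log_hr + z * se),
        reference_log_hr=ref,
    )
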