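"""Flexible parametric survival models on the log-cumulative-hazard scale.

The model is the Royston–Parmar form

    log H(t | x) = s(log t; gamma) + x' beta,

where ``s`` is a restricted cubic spline in log time.  With ``df = 1`` the
spline reduces to a straight line in log time and the family coincides with
the Weibull distribution (``gamma_0 = -shape * log(scale)``,
``gamma_1 = shape``).  Covariates act proportionally on the hazard, so
``beta`` are log hazard ratios.

The log likelihood for right-censored data (time ``t``, event indicator
``d``) is

    sum_i d_i * [log s'(log t_i) - log t_i + s(log t_i) + eta_i]
          - exp(s(log t_i) + eta_i)

with ``eta = offset + x' beta``.  ``s'`` denotes the derivative of the
spline with respect to log time; the hazard is positive only where
``s' > 0``, which the optimiser enforces implicitly through the
``log s'`` term at event times and which is re-checked on a grid after
fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "SplineBasisSpec",
    "FPSMFit",
    "rcs_basis",
    "rcs_derivative",
    "default_knots",
    "fit_fpsm",
    "predict_survival",
    "predict_risk",
    "predicted_hr",
]


@dataclass(frozen=True)
class SplineBasisSpec:
    """Restricted cubic spline specification on the log-time scale.

    ``df`` is the number of basis columns beyond the intercept; ``df = 2``
    therefore means one interior knot.  Interior knots must lie strictly
    inside the boundary knots and there must be exactly ``df - 1`` of them.
    """

    df: int
    boundary_knots: tuple[float, float]
    interior_knots: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError(f"df must be >= 1, got {self.df}")
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise ValueError(f"boundary knots must be ordered, got ({lo}, {hi})")
        ik = tuple(float(k) for k in self.interior_knots)
        if len(ik) != self.df - 1:
            raise ValueError(
                f"df={self.df} requires {self.df - 1} interior knots, got {len(ik)}"
            )
        if any(not lo < k < hi for k in ik):
            raise ValueError("interior knots must lie strictly inside boundary knots")
        if list(ik) != sorted(ik):
            raise ValueError("interior knots must be sorted")
        object.__setattr__(self, "interior_knots", ik)

    @property
    def all_knots(self) -> np.ndarray:
        lo, hi = self.boundary_knots
        return np.asarray([lo, *self.interior_knots, hi], dtype=float)


def default_knots(log_event_times: np.ndarray, df: int) -> SplineBasisSpec:
    """Knot rule: boundary knots at the min/max uncensored log event time,
    interior knots at equally spaced quantiles of the uncensored log event
    times (``df = 2`` puts the single interior knot at the median)."""
    x = np.asarray(log_event_times, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two uncensored event times to place knots")
    lo, hi = float(x.min()), float(x.max())
    if not lo < hi:
        raise ValueError("all event times identical; cannot place spline knots")
    probs = np.linspace(0.0, 1.0, df + 1)[1:-1]
    interior = tuple(float(q) for q in np.quantile(x, probs))
    return SplineBasisSpec(df=df, boundary_knots=(lo, hi), interior_knots=interior)


def _cube_pos(u: np.ndarray) -> np.ndarray:
    return np.where(u > 0.0, u, 0.0) ** 3


def rcs_basis(x: np.ndarray, spec: SplineBasisSpec) -> np.ndarray:
    """Restricted cubic spline basis (Durrleman–Simon form), without intercept.

    Column 0 is ``x`` itself; columns ``1 .. df-1`` are the restricted cubic
    terms, one per interior knot.  The resulting function space is linear
    beyond the boundary knots with continuous value, first and second
    derivatives everywhere.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    kmin, kmax = spec.boundary_knots
    cols = [x]
    span = kmax - kmin
    for kj in spec.interior_knots:
        lam = (kmax - kj) / span
        vj = (
            _cube_pos(x - kj)
            - lam * _cube_pos(x - kmin)
            - (1.0 - lam) * _cube_pos(x - kmax)
        ) / span**2  # scale by span^2 to keep terms on the scale of x
        cols.append(vj)
    return np.column_stack(cols)


def rcs_derivative(x: np.ndarray, spec: SplineBasisSpec) -> np.ndarray:
    """Derivative of each basis column with respect to ``x``."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    kmin, kmax = spec.boundary_knots
    cols = [np.ones_like(x)]
    span = kmax - kmin
    for kj in spec.interior_knots:
        lam = (kmax - kj) / span
        dj = 3.0 * (
            np.where(x > kj, x - kj, 0.0) ** 2
            - lam * np.where(x > kmin, x - kmin, 0.0) ** 2
            - (1.0 - lam) * np.where(x > kmax, x - kmax, 0.0) ** 2
        ) / span**2
        cols.append(dj)
    return np.column_stack(cols)


@dataclass
class FPSMFit:
    """A fitted flexible parametric survival model."""

    basis: SplineBasisSpec
    gamma: np.ndarray  # intercept + df spline coefficients
    beta: np.ndarray  # covariate log hazard ratios (may be empty)
    covariance: np.ndarray  # joint (gamma, beta) covariance
    loglik: float
    n: int
    n_events: int
    converged: bool
    n_restarts: int = 0
    monotone: bool = True
    message: str = ""
    covariate_names: tuple[str, ...] = field(default_factory=tuple)

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.gamma, self.beta])

    @property
    def beta_se(self) -> np.ndarray:
        k = len(self.gamma)
        d = np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))
        return d[k:]

    def spline(self, log_t: np.ndarray) -> np.ndarray:
        b = rcs_basis(log_t, self.basis)
        return self.gamma[0] + b @ self.gamma[1:]

    def spline_derivative(self, log_t: np.ndarray) -> np.ndarray:
        return rcs_derivative(log_t, self.basis) @ self.gamma[1:]

    def summary(self) -> dict:
        return {
            "df": self.basis.df,
            "knots": list(self.basis.all_knots),
            "gamma": list(self.gamma),
            "beta": dict(zip(self.covariate_names, map(float, self.beta))),
            "beta_se": dict(zip(self.covariate_names, map(float, self.beta_se))),
            "loglik": self.loglik,
            "n": self.n,
            "n_events": self.n_events,
            "converged": self.converged,
        }


def _prepare_design(
    time: np.ndarray,
    event: np.ndarray,
    covariates: np.ndarray | None,
    offset: np.ndarray | None,
):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.ndim != 1:
        raise ValueError("time must be one-dimensional")
    if np.any(time <= 0.0):
        raise ValueError("all times must be strictly positive")
    if event.shape != time.shape:
        raise ValueError("time and event must be aligned")
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    event = event.astype(float)
    if covariates is None:
        X = np.empty((time.size, 0))
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] != time.size:
            X = X.T
        if X.shape[0] != time.size:
            raise ValueError("covariate matrix not aligned with time vector")
        if not np.all(np.isfinite(X)):
            raise ValueError("covariates must be finite")
    if offset is None:
        off = np.zeros_like(time)
    else:
        off = np.asarray(offset, dtype=float)
        if off.shape != time.shape:
            raise ValueError("offset not aligned with time vector")
    return time, event, X, off


def _negloglik_and_grad(theta, B, dB, X, off, event, log_t):
    """Negative log likelihood and analytic gradient.

    ``B`` includes the intercept column; ``dB`` is the derivative of the
    non-intercept columns padded with a zero column for the intercept.
    """
    k = B.shape[1]
    gamma = theta[:k]
    beta = theta[k:]
    s = B @ gamma
    ds = dB @ gamma  # intercept column of dB is zero
    eta = off + (X @ beta if beta.size else 0.0)
    ds_ev = ds[event == 1.0]
    if ds_ev.size and np.min(ds_ev) <= 0.0:
        return np.inf, np.zeros_like(theta)
    logH = s + eta
    # guard exp overflow during line searches
    if np.max(logH) > 200.0:
        return np.inf, np.zeros_like(theta)
    H = np.exp(logH)
    ll = np.sum(event * (np.log(np.where(event == 1.0, ds, 1.0)) - log_t + logH)) - H.sum()
    w = event - H
    grad_gamma = (w[:, None] * B).sum(axis=0) + (
        (event / np.where(ds == 0.0, 1.0, ds))[:, None] * dB
    )[event == 1.0].sum(axis=0)
    grad_beta = X.T @ w if beta.size else np.empty(0)
    grad = np.concatenate([grad_gamma, grad_beta])
    return -ll, -grad


def _newton_polish(fun, res, grad_norm, ok, max_iter=15):
    """Damped Newton refinement after the quasi-Newton pass.

    BFGS can stop with a small but non-negligible gradient; a few Newton
    steps with the finite-difference Hessian push the gradient to machine
    noise, which keeps nested-model likelihoods properly ordered.
    """
    theta = res.x.copy()
    nll = res.fun
    for _ in range(max_iter):
        cur, grad = fun(theta)
        gnorm = float(np.max(np.abs(grad)))
        if not np.isfinite(cur) or gnorm < 1e-9 * max(1.0, abs(cur)):
            nll, grad_norm = cur, gnorm
            break
        H = _numeric_hessian(fun, theta)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        t = 1.0
        improved = False
        while t > 1e-4:
            cand_nll, _ = fun(theta - t * step)
            if cand_nll < cur:
                theta = theta - t * step
                nll = cand_nll
                improved = True
                break
            t /= 2.0
        if not improved:
            nll, grad_norm = cur, gnorm
            break
    final_nll, final_grad = fun(theta)
    if np.isfinite(final_nll) and final_nll <= res.fun:
        res.x = theta
        res.fun = final_nll
        res.jac = final_grad
        grad_norm = float(np.max(np.abs(final_grad)))
        ok = grad_norm < 1e-6 * max(1.0, abs(final_nll))
    return res, grad_norm, ok


def _numeric_hessian(fun, theta, eps=1e-5):
    p = theta.size
    H = np.zeros((p, p))
    for j in range(p):
        step = eps * max(1.0, abs(theta[j]))
        tp = theta.copy()
        tp[j] += step
        tm = theta.copy()
        tm[j] -= step
        _, gp = fun(tp)
        _, gm = fun(tm)
        H[:, j] = (gp - gm) / (2.0 * step)
    return 0.5 * (H + H.T)


def fit_fpsm(
    time: np.ndarray,
    event: np.ndarray,
    covariates: np.ndarray | None = None,
    df: int = 2,
    knots: SplineBasisSpec | None = None,
    offset: np.ndarray | None = None,
    covariate_names: Sequence[str] | None = None,
    max_restarts: int = 3,
) -> FPSMFit:
    """Maximum-likelihood fit of the flexible parametric survival model.

    Parameters
    ----------
    time, event
        Follow-up time (years, > 0) and 0/1 event indicator.
    covariates
        Optional n x p matrix; coefficients are log hazard ratios.
    df
        Spline degrees of freedom (basis terms beyond the intercept).
    knots
        Explicit knot specification; by default boundary knots sit at the
        min/max uncensored log event time and interior knots at quantiles.
    offset
        Known component of the linear predictor (coefficient fixed at 1),
        used for calibration-in-the-large.
    """
    time, event, X, off = _prepare_design(time, event, covariates, offset)
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("cannot fit a survival model with zero events")
    min_events = df + X.shape[1] + 2
    if n_events < min_events:
        raise ValueError(
            f"too few events ({n_events}) for df={df} and {X.shape[1]} covariates"
        )
    log_t = np.log(time)
    if knots is None:
        knots = default_knots(log_t[event == 1.0], df)
    elif knots.df != df:
        raise ValueError("knot specification df does not match requested df")

    B = np.column_stack([np.ones_like(log_t), rcs_basis(log_t, knots)])
    dB = np.column_stack([np.zeros_like(log_t), rcs_derivative(log_t, knots)])
    k = B.shape[1]

    # warm start: Weibull (df=1) fit, spline terms zero-padded; the df=1 fit
    # itself starts from the exponential-rate solution g0 = log(events / time)
    theta0 = np.zeros(k + X.shape[1])
    if df == 1:
        theta0[0] = np.log(n_events / time.sum())
        theta0[1] = 1.0
    else:
        base = fit_fpsm(
            time, event, covariates=covariates if X.shape[1] else None,
            df=1, offset=offset, max_restarts=max_restarts,
        )
        theta0[0], theta0[1] = base.gamma
        theta0[k:] = base.beta

    fun = lambda th: _negloglik_and_grad(th, B, dB, X, off, event, log_t)

    best = None
    rng = np.random.default_rng(0)
    n_restarts = 0
    for attempt in range(max_restarts + 1):
        start = theta0 if attempt == 0 else theta0 + rng.normal(0.0, 0.05, theta0.size)
        res = optimize.minimize(
            fun, start, jac=True, method="BFGS",
            options={"maxiter": 500, "gtol": 1e-8},
        )
        grad_norm = float(np.max(np.abs(res.jac)))
        ok = np.isfinite(res.fun) and grad_norm < 1e-6 * max(1.0, abs(res.fun))
        if best is None or res.fun < best[0].fun:
            best = (res, grad_norm, ok)
        if ok:
            break
        n_restarts = attempt + 1
    res, grad_norm, ok = best
    res, grad_norm, ok = _newton_polish(fun, res, grad_norm, ok)
    if not np.isfinite(res.fun):
        raise RuntimeError("flexible parametric fit failed to find a finite likelihood")
    if not ok and grad_norm > 1e-3 * max(1.0, abs(res.fun)):
        raise RuntimeError(
            f"flexible parametric fit did not converge (|grad| = {grad_norm:.3g})"
        )

    theta = res.x
    hess = _numeric_hessian(fun, theta)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    cov = 0.5 * (cov + cov.T)

    fit = FPSMFit(
        basis=knots,
        gamma=theta[:k].copy(),
        beta=theta[k:].copy(),
        covariance=cov,
        loglik=float(-res.fun),
        n=time.size,
        n_events=n_events,
        converged=ok,
        n_restarts=n_restarts,
        covariate_names=tuple(covariate_names or (f"x{j}" for j in range(X.shape[1]))),
    )

    # post-fit monotonicity check of s(log t) over the observed range
    grid = np.linspace(knots.boundary_knots[0], knots.boundary_knots[1], 200)
    if np.min(fit.spline_derivative(grid)) <= 0.0:
        fit = _monotone_refit(fit, fun, theta, grid, B, dB, X, off, event, log_t)
    return fit


def _monotone_refit(fit, fun, theta, grid, B, dB, X, off, event, log_t):
    """Log-barrier refit pushing s'(log t) positive over the checking grid.

    Unconstrained df=2 fits are almost always monotone; this fallback keeps
    the contract when they are not.
    """
    dG = np.column_stack([np.zeros_like(grid), rcs_derivative(grid, fit.basis)])
    k = len(fit.gamma)

    def barrier(th, mu):
        nll, grad = fun(th)
        if not np.isfinite(nll):
            return np.inf, grad
        ds = dG @ th[:k]
        if np.min(ds) <= 0.0:
            return np.inf, grad
        nll -= mu * np.sum(np.log(ds))
        grad[:k] -= mu * (dG / ds[:, None]).sum(axis=0)
        return nll, grad

    th = theta.copy()
    if np.min(dG @ th[:k]) <= 0.0:
        th[:k] = 0.0
        th[0] = fit.gamma[0]
        th[1] = max(fit.gamma[1], 0.1)
    for mu in (1e-2, 1e-4, 1e-6):
        res = optimize.minimize(
            barrier, th, args=(mu,), jac=True, method="BFGS",
            options={"maxiter": 300},
        )
        if np.isfinite(res.fun):
            th = res.x
    nll, _ = fun(th)
    hess = _numeric_hessian(fun, th)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    fit.gamma = th[:k].copy()
    fit.beta = th[k:].copy()
    fit.covariance = 0.5 * (cov + cov.T)
    fit.loglik = float(-nll)
    fit.monotone = bool(np.min(dG @ th[:k]) > 0.0)
    fit.message = "monotonicity enforced by log-barrier refit"
    return fit


def _eta(fit: FPSMFit, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None:
        if fit.beta.size:
            raise ValueError("fit has covariates; a covariate row is required")
        return np.zeros(1)
    x = np.atleast_2d(np.asarray(covariates, dtype=float))
    if x.shape[1] != fit.beta.size:
        raise ValueError(
            f"expected {fit.beta.size} covariates, got {x.shape[1]}"
        )
    return x @ fit.beta


def predict_survival(
    fit: FPSMFit, covariates: np.ndarray | None, t: float | np.ndarray,
    offset: np.ndarray | float = 0.0,
) -> np.ndarray:
    """S(t | x) = exp(-exp(s(log t) + eta)).

    ``t`` may be a scalar applied to every covariate row, or a vector
    aligned with the rows.  ``offset`` is added to the linear predictor
    (used by offset-calibrated models).
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr <= 0.0):
        raise ValueError("prediction times must be strictly positive")
    eta = _eta(fit, covariates) + offset
    s = fit.spline(np.log(t_arr))
    return np.exp(-np.exp(s + eta))


def predict_risk(
    fit: FPSMFit, covariates: np.ndarray | None, t: float | np.ndarray,
    offset: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Absolute risk by ``t``: 1 - S(t | x)."""
    return 1.0 - predict_survival(fit, covariates, t, offset=offset)


def predicted_hr(fit: FPSMFit, covariates_a, covariates_b) -> float:
    """Hazard ratio exp((x_a - x_b)' beta); time-constant by construction."""
    xa = np.asarray(covariates_a, dtype=float).ravel()
    xb = np.asarray(covariates_b, dtype=float).ravel()
    if xa.shape != xb.shape or xa.size != fit.beta.size:
        raise ValueError("covariate rows must match the fitted model")
    return float(np.exp((xa - xb) @ fit.beta))
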