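"""Weibull psychometric function: evaluation, fitting, goodness of fit.

The psychometric function relating a stimulus covariate x (here the depth
scale factor in percent) to proportion correct is

    Psi(x) = gamma + (1 - gamma - lambda) * (1 - exp(-(x/alpha)**beta))

with guess rate gamma, lapse rate lambda, inflection alpha (in covariate
units) and slope beta.  Fitting is bounded least squares on proportions,
multi-started over a grid of (alpha, beta) initial values to avoid local
minima; binomial weighting is applied when per-point trial counts are
supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.optimize import least_squares

__all__ = ["WeibullParams", "weibull_eval", "fit_weibull", "r_squared"]


@dataclass(frozen=True)
class WeibullParams:
    """Weibull psychometric parameters.

    gamma: guess rate in [0, 1); lam: lapse rate in [0, 1); alpha: point of
    inflection in covariate units (> 0); beta: slope (> 0).
    """

    gamma: float
    lam: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma < 1.0 and 0.0 <= self.lam < 1.0):
            raise ValueError("gamma and lam must lie in [0, 1)")
        if self.gamma + self.lam >= 1.0:
            raise ValueError("gamma + lam must be < 1")
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if not self.beta > 0:
            raise ValueError("beta must be > 0")


def weibull_eval(x: ArrayLike, p: WeibullParams) -> NDArray[np.float64] | float:
    """Evaluate Psi(x); accepts scalars or arrays, x >= 0."""
    x_arr = np.asarray(x, dtype=np.float64)
    if np.any(x_arr < 0):
        raise ValueError("x must be >= 0")
    out = p.gamma + (1.0 - p.gamma - p.lam) * (
        1.0 - np.exp(-((x_arr / p.alpha) ** p.beta))
    )
    return float(out) if np.isscalar(x) or x_arr.ndim == 0 else out


def _residuals(theta, xs, ys, weights):
    gamma, lam, alpha, beta = theta
    pred = gamma + (1.0 - gamma - lam) * (1.0 - np.exp(-((xs / alpha) ** beta)))
    return (pred - ys) * weights


def fit_weibull(
    xs: ArrayLike,
    ys: ArrayLike,
    n_per_point: ArrayLike | None = None,
) -> tuple[WeibullParams, float]:
    """Fit a Weibull psychometric function to mean proportions.

    Bounded least squares with gamma, lambda in [0, 0.5], alpha in
    (0, 2 max x], beta in [0.1, 10], multi-started over a coarse
    (alpha, beta) grid.  When ``n_per_point`` is given, residuals are
    weighted by sqrt(n).  Returns the best-fit parameters and the r^2 of
    the (unweighted) fit.
    """
    xs = np.asarray(xs, dtype=np.float64)
    ys = np.asarray(ys, dtype=np.float64)
    if xs.shape != ys.shape:
        raise ValueError("xs and ys must have the same shape")
    if np.unique(xs).size < 4:
        raise ValueError("at least 4 distinct x values are required")
    if np.any((ys < 0) | (ys > 1)):
        raise ValueError("ys must be proportions in [0, 1]")
    if n_per_point is not None:
        w = np.sqrt(np.asarray(n_per_point, dtype=np.float64))
    else:
        w = np.ones_like(xs)

    xmax = float(xs.max())
    lo = np.array([0.0, 0.0, 1e-6, 0.1])
    hi = np.array([0.5, 0.5, 2.0 * xmax, 10.0])
    g0 = float(np.clip(ys.min(), 0.0, 0.45))
    l0 = float(np.clip(1.0 - ys.max(), 0.0, 0.45))
    best = None
    for a0 in (0.2 * xmax, 0.4 * xmax, 0.8 * xmax):
        for b0 in (0.7, 1.5, 3.0):
            theta0 = np.clip([g0, l0, a0, b0], lo, hi)
            try:
                res = least_squares(
                    _residuals,
                    theta0,
                    args=(xs, ys, w),
                    bounds=(lo, hi),
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                )
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
    if best is None:
        raise RuntimeError("Weibull fit failed to converge from all starts")
    gamma, lam, alpha, beta = best.x
    # guard against gamma+lam hitting the simplex edge numerically
    if gamma + lam >= 1.0:
        lam = max(0.0, 1.0 - gamma - 1e-9)
    params = WeibullParams(gamma=float(gamma), lam=float(lam),
                           alpha=float(alpha), beta=float(beta))
    fitted = weibull_eval(xs, params)
    if np.allclose(ys, ys[0]):
        r2 = float("nan")
    else:
        r2 = r_squared(ys, fitted)
    return params, r2


def r_squared(observed: ArrayLike, fitted: ArrayLike) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    observed = np.asarray(observed, dtype=np.float64)
    fitted = np.asarray(fitted, dtype=np.float64)
    if observed.shape != fitted.shape or observed.size < 2:
        raise ValueError("observed and fitted must have equal length >= 2")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0 or math.isclose(ss_tot, 0.0, abs_tol=1e-30):
        raise ValueError("r^2 undefined for a constant observed vector")
    ss_res = float(np.sum((observed - fitted) ** 2))
    return 1.0 - ss_res / ss_tot
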