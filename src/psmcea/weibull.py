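"""Weibull survival curves: evaluation, hazard-ratio adjustment, fitting
and restricted means.

The parameterization throughout is

    S(t) = exp(-lambda * t**gamma),        t in months,

with scale ``lambda > 0`` (units month^-gamma) and shape ``gamma > 0``.
Under this form the hazard is ``h(t) = lambda * gamma * t**(gamma-1)``, so
multiplying the scale by a constant ``k`` multiplies the hazard by ``k``
uniformly in time: the family is closed under proportional hazards, and
``S_adj(t) = S(t)**k``.  That closure is what lets a single hazard ratio
turn a reference arm's curve into a comparator curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, special

from .errors import (
    FitFailureError,
    InsufficientDataError,
    InvalidArgumentError,
    NonIdentifiableError,
)

__all__ = [
    "WeibullCurve",
    "FitReport",
    "weibull_survival",
    "adjust_curve_by_hr",
    "fit_weibull_mle",
    "fit_weibull_to_km_points",
    "restricted_mean",
    "mean_survival",
]


@dataclass(frozen=True)
class WeibullCurve:
    """Scale/shape pair defining ``S(t) = exp(-scale * t**shape)``."""

    scale: float
    shape: float

    def __post_init__(self):
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise InvalidArgumentError(f"scale must be positive, got {self.scale}")
        if not (self.shape > 0 and math.isfinite(self.shape)):
            raise InvalidArgumentError(f"shape must be positive, got {self.shape}")

    def survival(self, t):
        """Vectorized survival function; accepts scalars or arrays."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise InvalidArgumentError("time must be non-negative")
        out = np.exp(-self.scale * np.power(t, self.shape))
        return float(out) if out.ndim == 0 else out

    def hazard(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise InvalidArgumentError("time must be non-negative")
        out = self.scale * self.shape * np.power(t, self.shape - 1.0)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FitReport:
    """Maximum-likelihood fit summary with information criteria.

    Invariants: ``aic == 2*n_params - 2*loglik`` and
    ``bic == n_params*ln(n_obs) - 2*loglik``.
    """

    curve: WeibullCurve
    loglik: float
    aic: float
    bic: float
    n_params: int
    n_obs: int

    def to_row(self) -> dict:
        """Flat key-value representation (one CSV row)."""
        return {
            "scale": self.curve.scale,
            "shape": self.curve.shape,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
        }


def weibull_survival(curve: WeibullCurve, t) -> float:
    """Survival probability ``exp(-scale * t**shape)`` at time ``t`` (months)."""
    return curve.survival(t)


def adjust_curve_by_hr(curve: WeibullCurve, hr: float,
                       direction: str = "divide") -> WeibullCurve:
    """Derive a comparator curve from a reference curve and a hazard ratio.

    With ``direction="divide"`` (default) the hazard ratio is read as
    HR(reference vs comparator), so the comparator hazard is
    ``reference hazard / hr``; an HR below one then makes the comparator's
    survival *worse*.  ``direction="multiply"`` applies the literal product
    ``scale * hr`` instead.  The shape is unchanged either way, and the
    adjusted curve satisfies ``S_adj(t) = S(t)**k`` where ``k`` is the
    multiplier actually applied to the scale.
    """
    if not (hr > 0 and math.isfinite(hr)):
        raise InvalidArgumentError(f"hazard ratio must be positive, got {hr}")
    if direction == "divide":
        k = 1.0 / hr
    elif direction == "multiply":
        k = hr
    else:
        raise InvalidArgumentError(
            f"direction must be 'divide' or 'multiply', got {direction!r}")
    return WeibullCurve(scale=curve.scale * k, shape=curve.shape)


def _neg_loglik(log_params, times, events, fixed_shape):
    if fixed_shape is None:
        lam = math.exp(log_params[0])
        gam = math.exp(log_params[1])
    else:
        lam = math.exp(log_params[0])
        gam = fixed_shape
    t_ev = times[events == 1]
    ll = np.sum(np.log(lam) + np.log(gam) + (gam - 1.0) * np.log(t_ev))
    ll -= lam * np.sum(np.power(times, gam))
    return -ll


def fit_weibull_mle(ipd, fixed_shape: float | None = None,
                    tol: float = 1e-8) -> FitReport:
    """Fit a Weibull curve to right-censored event-time records by maximum
    likelihood.

    The log-likelihood is the standard censored form
    ``sum_events ln(lambda*gamma*t^(gamma-1)) - sum_all lambda*t^gamma``.
    Optimization runs in log-parameter space by Nelder-Mead from the fixed
    start ``gamma=1``, ``lambda = n_events / sum(t)`` (the exponential MLE),
    which makes fits reproducible.  ``fixed_shape`` constrains the shape,
    giving the exponential sub-model when set to 1.
    """
    times = np.asarray(ipd.time, dtype=float)
    events = np.asarray(ipd.event, dtype=int)
    n_obs = len(times)
    if n_obs < 2:
        raise InsufficientDataError("need at least 2 records")
    n_events = int(events.sum())
    if n_events == 0:
        raise NonIdentifiableError("no events: the likelihood has no maximum")
    if np.any(times[events == 1] <= 0):
        raise InvalidArgumentError("event times must be strictly positive")

    lam0 = n_events / times.sum()
    if fixed_shape is None:
        x0 = np.array([math.log(lam0), 0.0])
    else:
        x0 = np.array([math.log(lam0)])
    res = optimize.minimize(
        _neg_loglik, x0, args=(times, events, fixed_shape),
        method="Nelder-Mead",
        options={"xatol": tol, "fatol": tol, "maxiter": 5000, "maxfev": 5000},
    )
    if not res.success:
        raise FitFailureError("Weibull MLE did not converge", diagnostics=res)

    lam = math.exp(res.x[0])
    gam = fixed_shape if fixed_shape is not None else math.exp(res.x[1])
    loglik = -float(res.fun)
    n_params = 1 if fixed_shape is not None else 2
    return FitReport(
        curve=WeibullCurve(scale=lam, shape=gam),
        loglik=loglik,
        aic=2 * n_params - 2 * loglik,
        bic=n_params * math.log(n_obs) - 2 * loglik,
        n_params=n_params,
        n_obs=n_obs,
    )


def fit_weibull_to_km_points(points) -> WeibullCurve:
    """Recover a Weibull curve from digitized survival coordinates.

    Ordinary least squares on the complementary-log-log scale: for each
    usable point, ``ln(-ln S) = ln(lambda) + gamma * ln(t)``, so a straight
    line through ``(ln t, ln(-ln S))`` yields the shape as slope and
    ``ln(lambda)`` as intercept.  Points with survival exactly 0 or 1 (and
    the t=0 anchor) carry no information on this scale and are excluded.
    Exact (noiseless) coordinates are inverted exactly.
    """
    t = np.asarray(points.time, dtype=float)
    s = np.asarray(points.survival, dtype=float)
    usable = (t > 0) & (s > 0) & (s < 1)
    if usable.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 points with 0 < survival < 1, got {int(usable.sum())}")
    x = np.log(t[usable])
    y = np.log(-np.log(s[usable]))
    slope, intercept = np.polyfit(x, y, 1)
    return WeibullCurve(scale=math.exp(intercept), shape=float(slope))


def restricted_mean(curve: WeibullCurve, horizon: float) -> float:
    """Area under the survival curve from 0 to ``horizon`` months.

    As the horizon grows this approaches the unrestricted mean
    ``Gamma(1 + 1/shape) * scale**(-1/shape)``.
    """
    if horizon < 0:
        raise InvalidArgumentError("horizon must be non-negative")
    if horizon == 0:
        return 0.0
    val, _ = integrate.quad(curve.survival, 0.0, horizon, limit=200)
    return float(val)


def mean_survival(curve: WeibullCurve) -> float:
    """Unrestricted mean ``Gamma(1 + 1/shape) * scale**(-1/shape)`` (months)."""
    return float(special.gamma(1.0 + 1.0 / curve.shape)
                 * curve.scale ** (-1.0 / curve.shape))
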