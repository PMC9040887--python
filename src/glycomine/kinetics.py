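"""Biochemical model fitting: single-turnover glycosylase time courses,
lag-time and colony-survival dose-response Hill fits, and fold changes.

Models
------
Glycosylase time course (enzyme in excess; the observed rate approximates
the chemistry step kcat)::

    P(t) = A * (1 - exp(-k t)),   k >= 0,  0 <= A <= 1.05

Lag-time dose response (growth inhibition)::

    lag([I]) = min_lag + (max_lag - min_lag) / (1 + (IC50/[I])^h)

Percent-survival dose response (the same 4-parameter Hill form with the
response decreasing in dose; the maximum sits at dose 0)::

    S([I]) = min_S + (max_S - min_S) / (1 + ([I]/IC50)^h)

At dose = IC50 either Hill curve predicts the exact midpoint of its min and
max. Fits are bounded nonlinear least squares with a deterministic
log-spaced multistart over k or IC50, so repeated fits of the same data are
identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FitError",
    "ExponentialFit",
    "Ic50Fit",
    "fit_single_exponential",
    "estimate_lag_time",
    "fit_ic50_lag",
    "fit_ic50_survival",
    "hill_lag",
    "hill_survival",
    "percent_survival",
    "fold_change",
]

_FTOL = 1e-10


class FitError(RuntimeError):
    """Non-convergence of a bounded least-squares fit; carries the best
    candidate parameters found."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


@dataclass
class ExponentialFit:
    k: float  # min^-1
    amplitude: float  # fraction product at plateau
    rss: float
    k_stderr: float = float("nan")
    amplitude_stderr: float = float("nan")
    k_is_lower_bound: bool = False  # reaction complete at earliest time point
    k_unidentifiable: bool = False  # no signal (A ~ 0)

    def predict(self, t):
        return self.amplitude * (1.0 - np.exp(-self.k * np.asarray(t, dtype=float)))


@dataclass
class Ic50Fit:
    ic50: float
    hill: float
    min_response: float
    max_response: float
    rss: float
    decreasing: bool = False
    stderr: dict = field(default_factory=dict)
    no_inhibition: bool = False

    def predict(self, dose):
        dose = np.asarray(dose, dtype=float)
        if self.decreasing:
            return hill_survival(dose, self.min_response, self.max_response,
                                 self.ic50, self.hill)
        return hill_lag(dose, self.min_response, self.max_response,
                        self.ic50, self.hill)


def hill_lag(dose, min_response, max_response, ic50, h):
    """Increasing Hill response; dose 0 maps to min_response exactly."""
    dose = np.asarray(dose, dtype=float)
    out = np.full(dose.shape, float(min_response))
    pos = dose > 0
    out[pos] = min_response + (max_response - min_response) / (
        1.0 + (ic50 / dose[pos]) ** h
    )
    return out


def hill_survival(dose, min_response, max_response, ic50, h):
    """Decreasing Hill response; dose 0 maps to max_response exactly."""
    dose = np.asarray(dose, dtype=float)
    return min_response + (max_response - min_response) / (
        1.0 + (dose / ic50) ** h
    )


def _stderr_from_jacobian(res, n: int, p: int) -> np.ndarray:
    dof = max(n - p, 1)
    s2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)


def fit_single_exponential(
    t: Sequence[float], y: Sequence[float], amplitude_max: float = 1.05
) -> ExponentialFit:
    """Least-squares fit of P(t) = A(1 - e^(-kt)) to a time course.

    When the first time point already sits at the plateau the rate is only
    bounded from below by the data and the fit is flagged
    ``k_is_lower_bound`` ("complete at the earliest time point"). An
    all-zero response yields A ~ 0 with ``k_unidentifiable`` set.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.ndim != 1 or t.size < 3:
        raise ValueError("need at least 3 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    a0 = float(np.clip(np.max(y), 1e-6, amplitude_max))
    if np.max(np.abs(y)) < 1e-9:
        return ExponentialFit(k=0.0, amplitude=0.0, rss=float(np.sum(y**2)),
                              k_unidentifiable=True)

    def resid(params):
        k, a = params
        return a * (1.0 - np.exp(-k * t)) - y

    t_scale = max(t[t > 0].min() if np.any(t > 0) else 1.0, 1e-9)
    best = None
    for k0 in np.geomspace(0.01 / t_scale, 100.0 / t_scale, 5):
        res = least_squares(
            resid, x0=[k0, a0], bounds=([0.0, 0.0], [np.inf, amplitude_max]),
            ftol=_FTOL, xtol=1e-12, gtol=1e-12,
        )
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        raise FitError("single-exponential fit did not converge",
                       best=None if best is None else best.x)
    k, a = best.x
    err = _stderr_from_jacobian(best, t.size, 2)
    plateau_at_first = y[0] >= 0.95 * a > 0
    return ExponentialFit(
        k=float(k),
        amplitude=float(a),
        rss=float(np.sum(best.fun**2)),
        k_stderr=float(err[0]),
        amplitude_stderr=float(err[1]),
        k_is_lower_bound=bool(plateau_at_first),
    )


def estimate_lag_time(t: Sequence[float], od: Sequence[float]) -> float:
    """Lag time of a growth curve by the tangent-intercept construction.

    The tangent at the point of maximal log-linear slope is intersected with
    the baseline OD; the crossing time is the lag. A curve that never
    exceeds twice its baseline is called "no growth" and returns the final
    time point (the maximal observable lag). Deterministic for fixed input.
    """
    t = np.asarray(t, dtype=float)
    od = np.asarray(od, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 points spanning growth onset")
    baseline = float(max(od[0], 1e-9))
    if np.max(od) < 2.0 * baseline:
        return float(t[-1])  # no-growth sentinel
    log_od = np.log(np.clip(od, 1e-12, None))
    best_slope, best_i = -np.inf, 1
    for i in range(1, t.size - 1):  # 3-point local slope
        sl = np.polyfit(t[i - 1 : i + 2], log_od[i - 1 : i + 2], 1)[0]
        if sl > best_slope:
            best_slope, best_i = sl, i
    if best_slope <= 0:
        return float(t[-1])
    lag = t[best_i] + (np.log(baseline) - log_od[best_i]) / best_slope
    return float(max(lag, 0.0))


def _fit_hill(
    doses: np.ndarray, response: np.ndarray, decreasing: bool
) -> Ic50Fit:
    lo, hi = float(np.min(response)), float(np.max(response))
    span0 = max(hi - lo, 1e-9)
    model = hill_survival if decreasing else hill_lag

    def resid(params):
        minr, span, log_ic50, h = params
        return model(doses, minr, minr + span, np.exp(log_ic50), h) - response

    pos = doses[doses > 0]
    if pos.size == 0:
        raise ValueError("need at least one positive dose")
    best = None
    for ic0 in np.geomspace(pos.min(), pos.max(), 5):
        for h0 in (1.0, 2.0):
            res = least_squares(
                resid,
                x0=[lo, span0, np.log(ic0), h0],
                bounds=([-np.inf, 0.0, np.log(pos.min() / 1e3), 0.05],
                        [np.inf, np.inf, np.log(pos.max() * 1e3), 50.0]),
                ftol=_FTOL, xtol=1e-12, gtol=1e-12,
            )
            if best is None or res.cost < best.cost:
                best = res
    if best is None or not best.success:
        raise FitError("Hill fit did not converge",
                       best=None if best is None else best.x)
    minr, span, log_ic50, h = best.x
    err = _stderr_from_jacobian(best, doses.size, 4)
    return Ic50Fit(
        ic50=float(np.exp(log_ic50)),
        hill=float(h),
        min_response=float(minr),
        max_response=float(minr + span),
        rss=float(np.sum(best.fun**2)),
        decreasing=decreasing,
        stderr={
            "min_response": float(err[0]),
            "span": float(err[1]),
            "ic50": float(np.exp(log_ic50) * err[2]),  # delta method from log scale
            "hill": float(err[3]),
        },
        no_inhibition=bool(span < 1e-6 * max(abs(hi), 1.0)),
    )


def fit_ic50_lag(doses: Sequence[float], lags: Sequence[float]) -> Ic50Fit:
    """Fit lag = min_lag + (max_lag - min_lag)/[1 + (IC50/dose)^h]."""
    doses = np.asarray(doses, dtype=float)
    lags = np.asarray(lags, dtype=float)
    if doses.size < 4:
        raise ValueError("need at least 4 doses (including 0 and a saturating dose)")
    if np.any(doses < 0) or np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be non-negative and strictly increasing")
    return _fit_hill(doses, lags, decreasing=False)


def fit_ic50_survival(doses: Sequence[float], survival: Sequence[float]) -> Ic50Fit:
    """Fit the decreasing Hill form to percent survival; IC50 is the dose of
    half-maximal survival. A response flat at its maximum is flagged
    ``no_inhibition``."""
    doses = np.asarray(doses, dtype=float)
    survival = np.asarray(survival, dtype=float)
    if doses.size < 4:
        raise ValueError("need at least 4 doses")
    if np.any(doses < 0) or np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be non-negative and strictly increasing")
    if np.ptp(survival) < 1e-9:
        return Ic50Fit(
            ic50=float("inf"), hill=float("nan"),
            min_response=float(survival[0]), max_response=float(survival[0]),
            rss=0.0, decreasing=True, no_inhibition=True,
        )
    return _fit_hill(doses, survival, decreasing=True)


def percent_survival(cfu_treated: float, cfu_untreated: float) -> float:
    """100 x CFU/mL(treated) / CFU/mL(untreated)."""
    if cfu_untreated <= 0:
        raise ValueError("untreated CFU/mL must be positive")
    return 100.0 * cfu_treated / cfu_untreated


def fold_change(ic50_a: float, ic50_b: float) -> float:
    """Ratio of two IC50 values (a / b)."""
    if ic50_a <= 0 or ic50_b <= 0:
        raise ValueError("IC50 values must be positive")
    return ic50_a / ic50_b
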