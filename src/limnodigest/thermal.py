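"""Thermofluor melt-curve fitting with a five-parameter sigmoid.

A thermal shift (thermofluor) assay tracks dye fluorescence as a protein
unfolds along a temperature ramp.  The transition is modeled with the
five-parameter logistic

    y(T) = L + (U - L) / (1 + exp(-k (T - m)))^d,

where L and U are the folded/unfolded fluorescence asymptotes, m positions
the transition, k is the slope and d an asymmetry exponent.  The melting
temperature Tm is reported as the midpoint -- the temperature where the
fitted curve crosses (L + U) / 2 -- which is robust to the particular sigmoid
parameterization (for d = 1 it coincides with m).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["MeltCurve", "MeltFitResult", "sigmoid_5pl", "tm_of_params", "fit_5pl", "tm_shift"]

TEMP_RANGE = (25.0, 95.0)


@dataclass(frozen=True)
class MeltCurve:
    """Fluorescence (a.u.) against a strictly increasing temperature grid (C)."""

    temperature: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.temperature, dtype=float)
        y = np.asarray(self.fluorescence, dtype=float)
        if t.ndim != 1 or y.shape != t.shape:
            raise ValueError("temperature and fluorescence must match in shape")
        if t.size < 10:
            raise ValueError("melt curve needs at least 10 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "fluorescence", y)


@dataclass(frozen=True)
class MeltFitResult:
    """Fitted 5PL parameters, their SDs, the midpoint Tm, and fit RMSE."""

    lower: float
    upper: float
    midpoint: float  # the m parameter, deg C
    slope: float
    asymmetry: float
    tm: float  # temperature where y = (L+U)/2, deg C
    tm_sd: float
    param_sd: tuple[float, float, float, float, float]
    rmse: float
    extrapolated: bool = False  # Tm outside the data range


def sigmoid_5pl(t, lower, upper, midpoint, slope, asymmetry):
    """Five-parameter logistic evaluated at temperature(s) t.

    Computed as exp(-d * log(1 + e^{-k(T-m)})) to avoid overflow for steep
    slopes far from the midpoint.
    """
    u = -slope * (np.asarray(t, dtype=float) - midpoint)
    return lower + (upper - lower) * np.exp(-asymmetry * np.logaddexp(0.0, u))


def tm_of_params(lower, upper, midpoint, slope, asymmetry) -> float:
    """Midpoint temperature where the 5PL crosses (lower + upper) / 2.

    Closed form: (1 + e^{-k(T-m)})^d = 2  =>  T = m - ln(2^{1/d} - 1) / k.
    """
    if slope == 0:
        raise ValueError("slope must be nonzero")
    return midpoint - math.log(2.0 ** (1.0 / asymmetry) - 1.0) / slope


def _initializations(t: np.ndarray, y: np.ndarray):
    """Three deterministic starts built from a lightly smoothed curve.

    The midpoint start comes from the half-range crossing of the smoothed
    trace (robust to point noise); the alternatives use the steepest-gradient
    temperature and a shallower slope.
    """
    win = max(min(7, y.size // 4), 1)
    ys = np.convolve(y, np.ones(win) / win, mode="same")
    lo, hi = float(np.min(ys)), float(np.max(ys))
    increasing = ys[-1] >= ys[0]
    half = (lo + hi) / 2.0
    above = ys >= half if increasing else ys <= half
    cross = np.argmax(above)  # first index past the half-transition
    m_cross = float(t[cross]) if above.any() else float(t[t.size // 2])
    m_grad = float(t[np.argmax(np.abs(np.gradient(ys, t)))])
    width = max((t[-1] - t[0]) / 10.0, 1.0)
    k0 = (4.0 / width) * (1.0 if increasing else -1.0)
    yield np.array([lo, hi, m_cross, k0, 1.0])
    yield np.array([lo, hi, m_grad, k0, 1.0])
    yield np.array([lo, hi, m_cross, 0.3 * k0, 1.0])


def fit_5pl(curve: MeltCurve) -> MeltFitResult:
    """Nonlinear least-squares 5PL fit; Tm solved as the half-transition point.

    Three deterministic initializations are tried and the best RMSE kept.
    Decreasing curves are handled by a negative slope.  A constant
    fluorescence trace is rejected.
    """
    t, y = curve.temperature, curve.fluorescence
    if np.ptp(y) == 0:
        raise ValueError("constant fluorescence: nothing to fit")

    span = float(np.ptp(y))
    lb = np.array([np.min(y) - span, np.min(y) - span, t[0] - 50.0, -10.0, 0.05])
    ub = np.array([np.max(y) + span, np.max(y) + span, t[-1] + 50.0, 10.0, 20.0])

    best = None
    errors = []
    for p0 in _initializations(t, y):
        p0 = np.clip(p0, lb + 1e-9, ub - 1e-9)
        try:
            sol = least_squares(
                lambda p: sigmoid_5pl(t, *p) - y, p0, bounds=(lb, ub), max_nfev=5000
            )
        except Exception as exc:  # pragma: no cover - scipy internal failure
            errors.append(str(exc))
            continue
        if not sol.success:
            errors.append(sol.message)
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(f"5PL fit failed from all starts: {errors}")

    lower, upper, midpoint, slope, asym = best.x
    rss = float(2.0 * best.cost)
    n = t.size
    rmse = math.sqrt(rss / n)
    sds = _param_sds(best.jac, rss, n)
    tm = tm_of_params(lower, upper, midpoint, slope, asym)
    tm_sd = _tm_sd(best.x, sds)
    extrapolated = not (t[0] <= tm <= t[-1])
    if extrapolated:
        warnings.warn(f"fitted Tm {tm:.1f} C lies outside the data range", stacklevel=2)
    if upper < lower:  # canonical ordering: report asymptotes as (low, high) signal
        lower, upper = upper, lower
    return MeltFitResult(
        lower=lower,
        upper=upper,
        midpoint=midpoint,
        slope=slope,
        asymmetry=asym,
        tm=tm,
        tm_sd=tm_sd,
        param_sd=tuple(sds),
        rmse=rmse,
        extrapolated=extrapolated,
    )


def _param_sds(jac: np.ndarray, rss: float, n: int) -> np.ndarray:
    p = jac.shape[1]
    dof = max(n - p, 1)
    cov = np.linalg.pinv(jac.T @ jac) * (rss / dof)
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


def _tm_sd(params: np.ndarray, sds: np.ndarray) -> float:
    """First-order propagation of parameter SDs through tm_of_params."""
    grad = np.zeros(5)
    base = tm_of_params(*params)
    for i in (2, 3, 4):  # Tm depends only on midpoint, slope, asymmetry
        step = max(abs(params[i]) * 1e-6, 1e-9)
        bumped = params.copy()
        bumped[i] += step
        grad[i] = (tm_of_params(*bumped) - base) / step
    return float(np.sqrt(np.sum((grad * sds) ** 2)))


def tm_shift(fit_a: MeltFitResult, fit_b: MeltFitResult) -> tuple[float, float]:
    """Tm(A) - Tm(B) with the SDs combined in quadrature."""
    return fit_a.tm - fit_b.tm, math.hypot(fit_a.tm_sd, fit_b.tm_sd)
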