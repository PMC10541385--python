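"""Gamma-variate model of the arterial first passage.

The bolus first passage through a feeding artery is modeled as

    C(t) = K * (t - AT)^alpha * exp(-(t - AT) / beta)   for t > AT, else 0

where AT is the bolus arrival time (s), K an amplitude scale (a.u.),
and alpha (dimensionless) and beta (s) shape the rise and decay. The
curve peaks at t = AT + alpha*beta with value K*(alpha*beta)^alpha *
exp(-alpha). This module evaluates the model and fits it to measured
curves; the fits serve both as training labels for the curve-correcting
CNN and as the clean arterial bolus of the digital phantom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .curves import ConcentrationCurve
from .errors import ConvergenceError, FitError, InputError

__all__ = ["GammaParams", "gamma_variate", "fit_gamma", "first_passage_window"]


@dataclass(frozen=True)
class GammaParams:
    """Parameters of the gamma-variate first-passage model.

    Attributes
    ----------
    K : float
        Constant scale factor (concentration a.u.), >= 0.
    AT : float
        Bolus arrival time (s), >= 0.
    alpha : float
        Shape exponent (dimensionless), > 0.
    beta : float
        Decay time constant (s), > 0.
    """

    K: float
    AT: float
    alpha: float
    beta: float

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0):
            raise InputError("alpha and beta must be > 0")
        if self.K < 0 or self.AT < 0:
            raise InputError("K and AT must be >= 0")
        if not np.isfinite(self.peak_time):
            raise InputError("implied peak time AT + alpha*beta must be finite")

    @property
    def peak_time(self) -> float:
        """Time of the curve maximum, AT + alpha*beta (s)."""
        return self.AT + self.alpha * self.beta

    @property
    def peak_value(self) -> float:
        """Model value at the peak, K*(alpha*beta)^alpha * exp(-alpha)."""
        return self.K * (self.alpha * self.beta) ** self.alpha * np.exp(-self.alpha)

    def as_array(self) -> np.ndarray:
        return np.array([self.K, self.AT, self.alpha, self.beta], dtype=float)


def gamma_variate(times: np.ndarray, params: GammaParams) -> ConcentrationCurve:
    """Evaluate the gamma-variate model on a time grid.

    The value is identically zero for t <= AT (pre-arrival baseline) and
    K*(t-AT)^alpha * exp(-(t-AT)/beta) afterwards.

    Raises
    ------
    InputError
        If the time grid is not strictly increasing.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or (t.size >= 2 and not np.all(np.diff(t) > 0)):
        raise InputError("time grid must be 1-D and strictly increasing")
    return ConcentrationCurve(t, _gamma_values(t, params.as_array()))


def _gamma_values(t: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Vectorized model evaluation on raw parameter vector [K, AT, alpha, beta]."""
    K, AT, alpha, beta = p
    dt = t - AT
    out = np.zeros_like(t, dtype=float)
    pos = dt > 0
    out[pos] = K * dt[pos] ** alpha * np.exp(-dt[pos] / beta)
    return out


def first_passage_window(curve: ConcentrationCurve) -> tuple[float, float]:
    """Default fit window: first sample to the first local minimum after the peak.

    The gamma-variate model describes only the first passage; the window
    excludes the recirculation bump that follows the post-peak trough.
    """
    v = curve.values
    j = int(np.argmax(v))
    end = curve.times[-1]
    for i in range(j + 1, len(v) - 1):
        if v[i] <= v[i - 1] and v[i] <= v[i + 1]:
            end = curve.times[i]
            break
    return float(curve.times[0]), float(end)


def _initial_guess(t: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Moment-based starting point for the nonlinear fit.

    AT is the first time the curve exceeds 10% of its peak; the peak time
    gives alpha*beta; a log-linearization at two points between arrival
    and peak separates alpha from beta.
    """
    peak = v.max()
    j_peak = int(np.argmax(v))
    above = np.nonzero(v > 0.10 * peak)[0]
    j0 = above[0] if above.size else 0
    AT = t[j0] - (t[1] - t[0]) if j0 > 0 else max(t[0] - (t[1] - t[0]), 0.0)
    AT = max(AT, 0.0)
    rise = max(t[j_peak] - AT, (t[1] - t[0]))
    alpha = 3.0
    beta = rise / alpha
    K = peak / max(rise**alpha * np.exp(-alpha), 1e-12)
    return np.array([K, AT, alpha, beta], dtype=float)


def fit_gamma(
    curve: ConcentrationCurve,
    fit_window: tuple[float, float] | None = None,
    *,
    flat_tol: float = 1e-9,
    max_iter: int = 500,
) -> tuple[GammaParams, dict]:
    """Fit the gamma-variate model to a curve by bounded nonlinear least squares.

    Parameters
    ----------
    curve : ConcentrationCurve
        Measured curve; needs >= 8 samples with nonzero dynamic range
        inside the window.
    fit_window : (float, float), optional
        Time interval to fit over. Default: from the first sample to the
        first local minimum after the global peak, i.e. the first-passage
        portion, excluding recirculation.
    flat_tol : float
        Minimum dynamic range (max - min) for the fit to be attempted.
    max_iter : int
        Maximum number of residual evaluations for the trust-region solver.

    Returns
    -------
    (GammaParams, dict)
        Fitted parameters and diagnostics: ``residual_norm`` (L2 norm of
        the residual inside the window), ``n_samples``, ``window``,
        ``success``.

    Raises
    ------
    FitError
        Flat or degenerate curve.
    ConvergenceError
        Solver did not converge; carries best-so-far parameters.
    """
    if fit_window is None:
        fit_window = first_passage_window(curve)
    lo, hi = fit_window
    sel = (curve.times >= lo) & (curve.times <= hi)
    t = curve.times[sel]
    v = curve.values[sel]
    if t.size < 8:
        raise FitError(f"need >= 8 samples inside the fit window, got {t.size}")
    if v.max() - v.min() < flat_tol:
        raise FitError("flat curve: dynamic range below tolerance")

    x0 = _initial_guess(t, v)
    span = t[-1] - t[0]
    lower = np.array([0.0, 0.0, 1e-3, 1e-3])
    upper = np.array([np.inf, t[-1], 50.0, 10.0 * span])
    x0 = np.clip(x0, lower + 1e-9, np.minimum(upper, 1e12) - 1e-9)

    def residuals(p):
        return _gamma_values(t, p) - v

    res = least_squares(
        residuals,
        x0,
        bounds=(lower, upper),
        xtol=1e-8,
        ftol=1e-10,
        gtol=1e-10,
        max_nfev=max_iter,
    )
    params = GammaParams(*[float(x) for x in res.x])
    diagnostics = {
        "residual_norm": float(np.linalg.norm(res.fun)),
        "n_samples": int(t.size),
        "window": (float(lo), float(hi)),
        "success": bool(res.status > 0),
    }
    if res.status <= 0:
        raise ConvergenceError(
            "gamma fit did not converge", best_params=params, diagnostics=diagnostics
        )
    return params, diagnostics
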