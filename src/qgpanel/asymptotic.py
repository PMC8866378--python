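"""Asymptotic-exponential curve fitting.

The same three-parameter curve

    y(x) = yf + (y0 - yf) * exp(-exp(log_alpha) * x)

describes both the decay of linkage disequilibrium with physical distance
(falling, y0 > yf) and the saturation of predictive ability with marker
count or training-population size (rising, y0 < yf).  ``y0`` is the value
at x = 0, ``yf`` the asymptote as x -> inf, and ``exp(log_alpha)`` the rate
constant (per unit of x).

Starting values are derived from the data in the style of a self-starting
regression: the asymptote from the far end of the x range, ``y0`` from the
near end, and the rate from a log-linearised fit of the residual decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


def asymp_curve(x, y0: float, yf: float, log_alpha: float):
    """Evaluate yf + (y0 - yf)·exp(−exp(log_alpha)·x)."""
    x = np.asarray(x, dtype=float)
    return yf + (y0 - yf) * np.exp(-np.exp(log_alpha) * x)


@dataclass
class AsymptoticFit:
    """Fitted parameters of the asymptotic-exponential curve."""

    y0: float
    yf: float
    log_alpha: float
    residual_sse: float
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    def __call__(self, x):
        return asymp_curve(x, self.y0, self.yf, self.log_alpha)

    def residuals(self) -> np.ndarray:
        return self.y - self(self.x)


def _self_start(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    n = len(xs)
    n_far = max(1, n // 4)
    yf0 = float(np.mean(ys[-n_far:]))
    y00 = float(ys[0])
    if abs(y00 - yf0) < 1e-12:
        # flat start; rate is unidentifiable, pick a scale from the x range
        span = max(float(xs[-1] - xs[0]), 1.0)
        return y00, yf0, float(np.log(1.0 / span))
    z = (ys - yf0) / (y00 - yf0)
    mask = z > 0.05
    la0 = np.log(3.0 / max(float(xs[-1]), 1.0))
    if mask.sum() >= 2 and np.ptp(xs[mask]) > 0:
        slope = np.polyfit(xs[mask], np.log(z[mask]), 1)[0]
        if slope < 0:
            la0 = float(np.log(-slope))
    return y00, yf0, float(la0)


def fit_asymptotic(x, y_vals, maxfev: int = 20000) -> AsymptoticFit:
    """Least-squares fit of the asymptotic-exponential curve.

    Supports both falling (y0 > yf) and rising (y0 < yf) data.  Requires at
    least 4 points with at least 3 distinct x values.

    Raises
    ------
    ValueError
        On too few points or degenerate x.
    RuntimeError
        On optimizer non-convergence (the message carries the starting
        values used, to aid diagnosis).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y_vals, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y_vals must be 1-D arrays of equal length")
    if len(x) < 4:
        raise ValueError(f"need >= 4 points, got {len(x)}")
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct x values")

    if np.ptp(y) < 1e-13:
        # constant response: y0 = yf = mean, any rate
        mean = float(np.mean(y))
        la = _self_start(x, y)[2]
        return AsymptoticFit(mean, mean, la, 0.0, x, y)

    p0 = _self_start(x, y)
    try:
        popt, _ = curve_fit(
            asymp_curve, x, y, p0=p0, maxfev=maxfev,
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
    except RuntimeError as exc:  # pragma: no cover - depends on data
        raise RuntimeError(
            f"asymptotic fit did not converge (start y0={p0[0]:.4g}, "
            f"yf={p0[1]:.4g}, log_alpha={p0[2]:.4g}): {exc}"
        ) from exc
    y0, yf, la = (float(v) for v in popt)
    sse = float(np.sum((y - asymp_curve(x, y0, yf, la)) ** 2))
    return AsymptoticFit(y0, yf, la, sse, x, y)
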