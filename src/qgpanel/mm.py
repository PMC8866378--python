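"""Spectral machinery for the single-random-effect mixed model.

    y = X b + u + e,   u ~ N(0, s2g·K),   e ~ N(0, s2e·I)

After one eigendecomposition K = U diag(d) U', rotating by U' makes the
covariance diagonal: Var(U'y) = s2g·diag(d + delta) with
delta = s2e/s2g.  Both the restricted (REML) and full (ML) likelihoods
then reduce to weighted least squares plus cheap scalar terms, and delta
is found by bounded 1-D optimisation on the log scale (grid bracket +
Brent refinement).  This is the standard efficient-mixed-model approach
used throughout the association scan, the permutation thresholds and
GBLUP variance estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

_LOG_DELTA_RANGE = (-12.0, 12.0)
_GRID_SIZE = 40


@dataclass
class VarianceComponents:
    sigma2_G: float
    sigma2_eps: float
    delta: float  # sigma2_eps / sigma2_G
    loglik_reml: float


def eigendecompose(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (clipped at 0) and eigenvectors of a PSD kinship."""
    d, U = np.linalg.eigh(K)
    return np.clip(d, 0.0, None), U


def _gls(delta: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray):
    """Weighted LS of rotated y on rotated X; returns (rss, beta, logdet
    of X'WX, sum log(d+delta))."""
    w = 1.0 / (d + delta)
    Xw = Xt * w[:, None]
    XtWX = Xt.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ yt)
    resid = yt - Xt @ beta
    rss = float(np.sum(w * resid ** 2))
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1 X not positive definite")
    return rss, beta, logdet, float(np.sum(np.log(d + delta)))


def reml_neg2ll(delta: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    n, p = Xt.shape
    rss, _, logdet_xwx, logdet_v = _gls(delta, d, yt, Xt)
    s2g = rss / (n - p)
    return (
        (n - p) * (np.log(2.0 * np.pi * s2g) + 1.0) + logdet_v + logdet_xwx
    )


def ml_neg2ll(delta: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    n = Xt.shape[0]
    rss, _, _, logdet_v = _gls(delta, d, yt, Xt)
    s2g = rss / n
    return n * (np.log(2.0 * np.pi * s2g) + 1.0) + logdet_v


def _optimize_delta(obj) -> float:
    """Grid bracket over log-delta, then bounded Brent refinement."""
    grid = np.linspace(*_LOG_DELTA_RANGE, _GRID_SIZE)
    vals = np.array([obj(g) for g in grid])
    if not np.isfinite(vals).any():
        raise RuntimeError(
            "variance-ratio optimisation failed on the whole grid: "
            f"log-delta in {_LOG_DELTA_RANGE}"
        )
    k = int(np.nanargmin(np.where(np.isfinite(vals), vals, np.nan)))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x) if res.fun <= vals[k] else float(grid[k])


def fit_variance_components(
    y: np.ndarray,
    X: np.ndarray,
    d: np.ndarray,
    U: np.ndarray,
    method: str = "reml",
) -> tuple[VarianceComponents, np.ndarray]:
    """Estimate (s2g, s2e) by REML or ML on the rotated model.

    Returns the components and the GLS fixed-effect estimates at the
    optimum.  Raises on zero phenotypic variance.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if np.var(y) < 1e-14:
        raise ValueError("phenotype has zero variance")
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need n >= p + 2 (n={n}, p={p})")
    yt = U.T @ y
    Xt = U.T @ X
    obj_fn = reml_neg2ll if method == "reml" else ml_neg2ll

    def obj(log_delta: float) -> float:
        try:
            return obj_fn(np.exp(log_delta), d, yt, Xt)
        except np.linalg.LinAlgError:
            return np.inf

    log_delta = _optimize_delta(obj)
    delta = float(np.exp(log_delta))
    rss, beta, _, _ = _gls(delta, d, yt, Xt)
    dof = n - p if method == "reml" else n
    s2g = rss / dof
    s2e = delta * s2g
    neg2 = obj_fn(delta, d, yt, Xt)
    return VarianceComponents(float(s2g), float(s2e), delta, -0.5 * neg2), beta


def loglik_at(y: np.ndarray, X: np.ndarray, d: np.ndarray, U: np.ndarray,
              method: str = "ml") -> float:
    """Profile log-likelihood maximised over (delta, s2g, beta)."""
    vc, _ = fit_variance_components(y, X, d, U, method=method)
    return vc.loglik_reml
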