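"""Stage 1: per-genotype trait means from multi-environment subsampled records.

Model (equivalent to a randomized complete block design with subsampling):

    Y_ijl = mu + G_i + E_j + GE_ij + eps_ijl,
    GE_ij ~ N(0, sigma2_ge),  eps_ijl ~ N(0, sigma2_eps),

with genotype (G_i) and environment (E_j, the location × replicate
combination) fixed and the genotype × environment interaction random to
absorb unequal subsampling.  REML is computed on the cell-collapsed form:
within-cell deviations carry only sigma2_eps, while cell means carry
sigma2_ge + sigma2_eps/n_cell, so the restricted likelihood reduces to a
weighted regression over cells plus a pooled within-cell sum of squares.
Only the ratio lambda = sigma2_ge/sigma2_eps needs numerical optimisation
(bounded 1-D search); sigma2_eps is profiled in closed form.

Genotype means are estimated marginal means: fixed-effect predictions
averaged with equal weight over environment levels (sum-to-zero
environment contrasts make this the genotype coefficient itself, on the
response scale including mu).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar


@dataclass
class Stage1Fit:
    genotype_means: pd.Series  # indexed by genotype_id, response scale
    sigma2_ge: float
    sigma2_eps: float
    loglik_reml: float
    trait: str


def _cell_design(genos: pd.Index, envs: pd.Index, cell_g: np.ndarray,
                 cell_e: np.ndarray) -> np.ndarray:
    """Cell-level design: genotype one-hot + sum-to-zero env contrasts."""
    n_g, n_e = len(genos), len(envs)
    X = np.zeros((len(cell_g), n_g + n_e - 1))
    X[np.arange(len(cell_g)), cell_g] = 1.0
    for j in range(n_e - 1):
        X[cell_e == j, n_g + j] = 1.0
    X[cell_e == n_e - 1, n_g:] = -1.0
    return X


def fit_stage1(records: pd.DataFrame, trait: str) -> Stage1Fit:
    """REML fit of the stage-1 model for one trait.

    Requires >= 2 environments; with a single environment the model falls
    back to raw genotype means (sigma2_ge is not estimable) with a warning.
    """
    df = records.loc[records["trait"] == trait]
    if df.empty:
        raise ValueError(f"no records for trait {trait!r}")
    if df["value"].isna().any():
        raise ValueError("missing trait values are not allowed")

    genos = pd.Index(pd.unique(df["genotype_id"]))
    envs = pd.Index(pd.unique(df["environment"]))

    if len(envs) < 2:
        warnings.warn(
            "single environment: sigma2_ge not estimable, "
            "falling back to raw genotype means",
            stacklevel=2,
        )
        means = df.groupby("genotype_id", sort=False)["value"].mean()
        resid = df["value"] - df["genotype_id"].map(means)
        dof = max(len(df) - len(genos), 1)
        return Stage1Fit(means.reindex(genos), np.nan,
                         float((resid ** 2).sum() / dof), np.nan, trait)

    cells = df.groupby(["genotype_id", "environment"], sort=False)["value"]
    cell_n = cells.size().to_numpy(dtype=float)
    cell_mean = cells.mean().to_numpy()
    sse_within = float(((df["value"] - cells.transform("mean")) ** 2).sum())
    keys = cells.size().index
    cell_g = genos.get_indexer(keys.get_level_values(0))
    cell_e = envs.get_indexer(keys.get_level_values(1))

    X = _cell_design(genos, envs, cell_g, cell_e)
    N = len(df)
    p = X.shape[1]

    def profile(log_lam: float):
        lam = np.exp(log_lam)
        w = cell_n / (1.0 + cell_n * lam)  # weights for cell means
        Xw = X * np.sqrt(w)[:, None]
        yw = cell_mean * np.sqrt(w)
        XtX = Xw.T @ Xw
        beta = np.linalg.solve(XtX, Xw.T @ yw)
        wrss = float(((yw - Xw @ beta) ** 2).sum())
        R = sse_within + wrss
        s2e = R / (N - p)
        sign, logdet_m = np.linalg.slogdet(XtX)
        if sign <= 0:
            return np.inf, beta, s2e
        neg2l = (
            (N - p) * (np.log(s2e) + 1.0)
            + float(np.sum(np.log1p(cell_n * lam)))
            + logdet_m
            + (N - p) * np.log(2.0 * np.pi)
        )
        return neg2l, beta, s2e

    res = minimize_scalar(
        lambda t: profile(t)[0], bounds=(-18.0, 12.0), method="bounded",
        options={"xatol": 1e-10},
    )
    neg2l, beta, s2e = profile(res.x)
    if not np.isfinite(neg2l):
        raise np.linalg.LinAlgError(
            "stage-1 system is not positive definite (disconnected design?)"
        )
    lam = float(np.exp(res.x))
    s2ge = lam * s2e
    if lam < 2e-8:  # boundary: effectively zero interaction variance
        s2ge = 0.0
    means = pd.Series(beta[: len(genos)], index=genos, name=trait)
    return Stage1Fit(means, s2ge, float(s2e), -0.5 * neg2l, trait)


def fit_all_traits(records: pd.DataFrame) -> dict[str, Stage1Fit]:
    """Fit each trait independently; returns {trait: Stage1Fit}."""
    return {t: fit_stage1(records, t) for t in pd.unique(records["trait"])}


def genotype_means_frame(fits: dict[str, Stage1Fit]) -> pd.DataFrame:
    """Tidy (genotype_id, trait, mean) frame across traits."""
    rows = []
    for trait, fit in fits.items():
        for g, m in fit.genotype_means.items():
            rows.append((g, trait, m))
    return pd.DataFrame(rows, columns=["genotype_id", "trait", "mean"])
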