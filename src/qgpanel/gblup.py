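"""GBLUP: genomic breeding values, prediction-error variance, cross-validation.

Model: y = 1·mu + g + e with g ~ N(0, s2g·A) over *all* accessions in the
relationship matrix A and e ~ N(0, s2e·I) on the phenotyped subset.
Variance components are estimated by REML on the observed subset (spectral
form, see :mod:`qgpanel.mm`); breeding values for every accession —
including unphenotyped ones — follow from the conditional multivariate
normal ĝ = s2g·A[:, obs]·P·y, where P is the projection form of
V⁻¹ = (s2g·A_obs + s2e·I)⁻¹ that absorbs the estimated mean.  The
prediction-error variance PEV_i = s2g·A_ii − s2g²·aᵢ'P aᵢ is the g-block
diagonal of the inverse mixed-model-equation coefficient matrix (times
s2e), and reliability_i = 1 − PEV_i/(s2g·A_ii).

Predictive ability is estimated by randomized masking cross-validation:
per replicate a fraction of the phenotyped accessions is masked, the model
refit on the rest, and the masked accessions' GEBVs correlated (Pearson)
with their held-out genotype means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import mm
from .kinship import KinshipMatrix


@dataclass
class GBLUPFit:
    mu: float
    sigma2_g: float
    sigma2_e: float
    gebv: pd.Series         # all accessions in A
    pev: pd.Series
    reliability: pd.Series
    loglik_reml: float


@dataclass
class CVResult:
    per_rep_correlations: list[float]
    mean_ability: float
    sd_ability: float
    n_reps: int
    seed: Optional[int]
    vp_fraction: Optional[float] = None
    vp_ids_per_rep: Optional[list] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rep": np.arange(1, len(self.per_rep_correlations) + 1),
             "ability": self.per_rep_correlations}
        )


def fit_gblup(y_observed: pd.Series, A: KinshipMatrix) -> GBLUPFit:
    """Fit GBLUP from phenotypes on a (subset of) accessions in A."""
    obs_ids = list(y_observed.index)
    if len(obs_ids) == 0:
        raise ValueError("no observed phenotypes")
    all_ids = A.accession_ids
    lookup = {a: i for i, a in enumerate(all_ids)}
    try:
        obs_idx = np.array([lookup[a] for a in obs_ids])
    except KeyError as exc:
        raise KeyError(f"accession {exc.args[0]!r} absent from kinship") from exc
    y = y_observed.to_numpy(dtype=float)
    K_obs = A.values[np.ix_(obs_idx, obs_idx)]
    n_obs = len(obs_idx)

    if np.var(y) < 1e-14:
        zeros = pd.Series(0.0, index=all_ids)
        return GBLUPFit(float(np.mean(y)), 0.0, 0.0, zeros.copy(),
                        zeros.copy(), zeros.copy(), np.nan)

    d, U = mm.eigendecompose(K_obs)
    X = np.ones((n_obs, 1))
    vc, beta = mm.fit_variance_components(y, X, d, U, method="reml")
    s2g, s2e = vc.sigma2_G, vc.sigma2_eps
    mu = float(beta[0])

    # projection form of V^-1 absorbing the estimated mean
    V = s2g * K_obs + s2e * np.eye(n_obs)
    Vinv = np.linalg.inv(V)
    one = np.ones((n_obs, 1))
    ViX = Vinv @ one
    P = Vinv - ViX @ ViX.T / (one.T @ ViX).item()

    A_cross = A.values[:, obs_idx]          # n_all × n_obs
    gebv = s2g * A_cross @ (P @ y)
    APAt = (A_cross @ P) * A_cross          # row i: a_i' P ∘ a_i
    quad = APAt.sum(axis=1)
    diag_A = np.diag(A.values)
    pev = s2g * diag_A - s2g ** 2 * quad
    pev = np.clip(pev, 0.0, None)
    denom = s2g * diag_A
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(denom > 1e-12, 1.0 - pev / denom, 0.0)
    rel = np.clip(rel, 0.0, 1.0)
    return GBLUPFit(
        mu, float(s2g), float(s2e),
        pd.Series(gebv, index=all_ids),
        pd.Series(pev, index=all_ids),
        pd.Series(rel, index=all_ids),
        vc.loglik_reml,
    )


def _ability(fit: GBLUPFit, y: pd.Series, vp_ids) -> float:
    pred = fit.gebv.loc[vp_ids].to_numpy()
    obs = y.loc[vp_ids].to_numpy()
    if np.std(pred) < 1e-14 or np.std(obs) < 1e-14:
        return 0.0
    return float(np.corrcoef(pred, obs)[0, 1])


def cross_validate(
    y: pd.Series,
    A: KinshipMatrix,
    vp_fraction: float = 0.10,
    n_reps: int = 100,
    seed: int = 0,
) -> CVResult:
    """Randomized-masking cross-validation (mask ``vp_fraction``,
    ``n_reps`` replicates; defaults mask 10% a hundred times)."""
    if not (0.0 < vp_fraction < 1.0):
        raise ValueError("vp_fraction must be in (0, 1)")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    ids = np.asarray(y.index, dtype=object)
    n_vp = int(round(vp_fraction * len(ids)))
    cors, vp_sets = [], []
    for _ in range(n_reps):
        vp = rng.choice(ids, size=n_vp, replace=False)
        if len(vp) < 3:
            warnings.warn("validation set smaller than 3; replicate skipped",
                          stacklevel=2)
            continue
        tp_mask = ~np.isin(ids, vp)
        fit = fit_gblup(y.loc[ids[tp_mask]], A)
        cors.append(_ability(fit, y, vp))
        vp_sets.append(list(vp))
    return CVResult(cors, float(np.mean(cors)) if cors else np.nan,
                    float(np.std(cors, ddof=1)) if len(cors) > 1 else 0.0,
                    len(cors), seed, vp_fraction=vp_fraction,
                    vp_ids_per_rep=vp_sets)


def cross_validate_fixed(
    y: pd.Series,
    A: KinshipMatrix,
    tp_ids: Sequence,
    vp_ids: Sequence,
) -> CVResult:
    """One cross-validation evaluation with caller-specified TP/VP
    membership; pass lists-of-lists for several replicates."""
    if tp_ids and isinstance(tp_ids[0], (list, tuple, np.ndarray)):
        reps = list(zip(tp_ids, vp_ids))
    else:
        reps = [(tp_ids, vp_ids)]
    known = set(y.index)
    cors, vp_sets = [], []
    for tp, vp in reps:
        tp, vp = list(tp), list(vp)
        if set(tp) & set(vp):
            raise ValueError("TP and VP overlap")
        unknown = (set(tp) | set(vp)) - known
        if unknown:
            raise ValueError(f"unknown accession ids: {sorted(unknown)[:5]}")
        fit = fit_gblup(y.loc[tp], A)
        cors.append(_ability(fit, y, vp))
        vp_sets.append(vp)
    return CVResult(cors, float(np.mean(cors)),
                    float(np.std(cors, ddof=1)) if len(cors) > 1 else 0.0,
                    len(cors), None, vp_ids_per_rep=vp_sets)
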