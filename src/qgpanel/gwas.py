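"""Q+K mixed-model association scan with permutation thresholds.

The scan model is

    y = X b + s·tau + u + e,   u ~ N(0, s2G·K),   e ~ N(0, s2e·I),

where y are stage-1 genotype means, X holds the intercept plus the first
marker-PC score(s) (population structure), s is the tested marker's
coding (additive = dosage; dominance = heterozygosity indicator) and K is
the unscaled realized relationship matrix.  Variance components are
estimated once under the no-marker null (the P3D shortcut) and the
variance *ratio* is then held fixed for every marker test; the residual
scale is re-estimated per marker from its own generalized-least-squares
fit, so each marker test is an exact t-test within the fixed correlation
structure (and reduces to the ordinary OLS t-test when K = I).

Genome-wide significance uses permutation: the phenotype (with its
covariate rows) is permuted against the genotypes, the scan repeated, and
the threshold taken as the empirical (1 − alpha) quantile of the per-
permutation maximum LOD, controlling the family-wise error rate.

Significant markers are grouped into peaks by physical proximity; each
peak's contribution is then quantified by backward elimination on the
deviance d = 2(LL_f − LL_r) between ML fits with and without the peak's
representative marker, with p-values from the upper tail of chi² at
df = peak member count and partial R² = 1 − exp(−d/n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import mm
from .genotypes import GenotypeMatrix, marker_pca
from .kinship import KinshipMatrix, gwas_kinship

_MIN_SWS = 1e-12


@dataclass
class ScanModel:
    """Aligned inputs for the association scan."""

    y: np.ndarray
    X: np.ndarray  # intercept + structure covariates
    K: KinshipMatrix
    accession_ids: np.ndarray
    coding: str = "additive"
    _eig: Optional[tuple[np.ndarray, np.ndarray]] = field(default=None, repr=False)

    def __post_init__(self):
        n = len(self.y)
        if self.X.shape[0] != n or self.K.values.shape[0] != n:
            raise ValueError("y, X and K must share accession ordering")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("X is not full column rank")
        if self.coding not in ("additive", "dominance"):
            raise ValueError(f"unknown coding {self.coding!r}")

    @property
    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        if self._eig is None:
            self._eig = mm.eigendecompose(self.K.values)
        return self._eig


def make_scan_model(
    genotype_means: pd.Series,
    G: GenotypeMatrix,
    n_pcs: int = 1,
    coding: str = "additive",
    K: Optional[KinshipMatrix] = None,
) -> ScanModel:
    """Align genotype means with the marker panel; covariates are the
    intercept plus the first ``n_pcs`` marker-PC scores."""
    y = genotype_means.reindex(G.accession_ids)
    if y.isna().any():
        missing = list(y.index[y.isna()][:5])
        raise ValueError(f"genotype means missing for accessions {missing}")
    cols = [np.ones(G.n_accessions)]
    if n_pcs > 0:
        cols.append(marker_pca(G, n_components=n_pcs).scores)
    X = np.column_stack(cols)
    if K is None:
        K = gwas_kinship(G)
    return ScanModel(y.to_numpy(dtype=float), X, K, G.accession_ids.copy(),
                     coding)


def marker_coding(G: GenotypeMatrix, coding: str) -> np.ndarray:
    """Additive (dosage) or dominance (heterozygote indicator) coding."""
    if coding == "additive":
        return G.dosage
    dos = G.dosage
    if not np.allclose(dos, np.rint(dos)):
        warnings.warn("fractional dosages rounded for dominance coding",
                      stacklevel=2)
        dos = np.rint(dos)
    return (dos == 1).astype(float)


@dataclass
class ScanResult:
    table: pd.DataFrame  # marker_id, chrom, pos, effect, se, score, LOD, constant
    threshold_lod: Optional[float] = None
    n_permutations: int = 0
    vc: Optional[mm.VarianceComponents] = None


def null_reml(model: ScanModel) -> mm.VarianceComponents:
    """P3D step: REML variance components under the no-marker model."""
    d, U = model.eig
    vc, _ = mm.fit_variance_components(model.y, model.X, d, U, method="reml")
    return vc


def _scan_stats(delta: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray,
                St: np.ndarray):
    """Vectorised per-marker GLS t-tests with the variance ratio fixed.

    Returns (tau, se, tstat, lod, constant_mask); the residual scale is
    re-estimated per marker (df = n − p − 1).
    """
    n, p = Xt.shape
    w = 1.0 / (d + delta)
    Xw = Xt * w[:, None]
    M = Xt.T @ Xw
    Minv = np.linalg.inv(M)
    a0 = Xw.T @ yt
    yWy = float(np.sum(w * yt ** 2))
    rss0 = yWy - a0 @ Minv @ a0

    A = Xw.T @ St                      # p × m
    sWs = np.einsum("ij,ij->j", St, St * w[:, None])
    sWy = St.T @ (w * yt)
    MA = Minv @ A
    s_ws = sWs - np.einsum("ij,ij->j", A, MA)
    s_wy = sWy - A.T @ (Minv @ a0)

    constant = s_ws < _MIN_SWS
    s_ws_safe = np.where(constant, 1.0, s_ws)
    tau = s_wy / s_ws_safe
    rss = np.clip(rss0 - s_wy ** 2 / s_ws_safe, 1e-300, None)
    df = n - p - 1
    sigma2 = rss / df
    se = np.sqrt(sigma2 / s_ws_safe)
    tstat = tau / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), df)
    lod = -np.log10(np.clip(pval, 1e-300, None))
    tau[constant] = np.nan
    se[constant] = np.nan
    tstat[constant] = 0.0
    lod[constant] = 0.0
    return tau, se, tstat, lod, constant


def scan(model: ScanModel, G: GenotypeMatrix,
         vc: mm.VarianceComponents) -> ScanResult:
    """Single-marker scan with P3D variance ratio ``vc.delta``.

    Constant markers get LOD 0 and are flagged rather than failing.
    """
    d, U = model.eig
    yt = U.T @ model.y
    Xt = U.T @ model.X
    St = U.T @ marker_coding(G, model.coding)
    tau, se, tstat, lod, constant = _scan_stats(vc.delta, d, yt, Xt, St)
    table = pd.DataFrame(
        {
            "marker_id": G.marker_ids,
            "chrom": G.chrom.astype(str),
            "pos": G.pos,
            "effect": tau,
            "se": se,
            "score": tstat,
            "LOD": lod,
            "constant": constant,
        }
    )
    return ScanResult(table, vc=vc)


@dataclass
class PermutationThreshold:
    threshold_lod: float
    max_lods: np.ndarray
    n_perm: int
    alpha: float
    seed: int


def permutation_threshold(
    model: ScanModel,
    G: GenotypeMatrix,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PermutationThreshold:
    """FWER-controlling LOD threshold from phenotype permutations.

    y and its covariate rows are permuted jointly against (G, K); the
    variance ratio is re-estimated for each permutation (cheap, the
    eigendecomposition is reused) and the genome-wide maximum LOD
    recorded.  The threshold is the empirical (1 − alpha) quantile.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    rng = np.random.default_rng(seed)
    d, U = model.eig
    St = U.T @ marker_coding(G, model.coding)
    n = len(model.y)
    max_lods = np.empty(n_perm)
    for r in range(n_perm):
        perm = rng.permutation(n)
        y_p = model.y[perm]
        X_p = model.X[perm]
        yt = U.T @ y_p
        Xt = U.T @ X_p
        vc, _ = mm.fit_variance_components(y_p, X_p, d, U, method="reml")
        _, _, _, lod, _ = _scan_stats(vc.delta, d, yt, Xt, St)
        max_lods[r] = lod.max()
    threshold = float(np.quantile(max_lods, 1.0 - alpha))
    return PermutationThreshold(threshold, max_lods, n_perm, alpha, seed)


@dataclass
class Peak:
    chrom: str
    representative_marker: str
    member_markers: list
    lod: float
    effect: float
    position: int
    d: Optional[float] = None
    p_collapse: Optional[float] = None
    partial_r2: Optional[float] = None
    n: Optional[int] = None


def call_peaks(result: ScanResult, merge_window_bp: int = 1_000_000) -> list[Peak]:
    """Group markers above threshold into peaks per chromosome.

    Two significant markers join the same peak iff their gap is at most
    ``merge_window_bp``.  The representative is the highest-LOD member
    (ties broken by smaller position).
    """
    if result.threshold_lod is None:
        raise ValueError("scan result carries no threshold")
    sig = result.table.loc[result.table["LOD"] > result.threshold_lod]
    peaks: list[Peak] = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        gaps = grp["pos"].diff().to_numpy()
        group_id = np.cumsum(np.where(np.isnan(gaps) | (gaps <= merge_window_bp), 0, 1))
        for _, members in grp.groupby(group_id):
            best = members.sort_values(["LOD", "pos"], ascending=[False, True]).iloc[0]
            peaks.append(
                Peak(
                    chrom=str(chrom),
                    representative_marker=str(best["marker_id"]),
                    member_markers=list(members["marker_id"]),
                    lod=float(best["LOD"]),
                    effect=float(best["effect"]),
                    position=int(best["pos"]),
                )
            )
    peaks.sort(key=lambda p: (p.chrom, p.position))
    return peaks


def partial_r2_from_deviance(d: float, n: int) -> float:
    """Variance fraction attributed to a deviance d: R² = 1 − e^(−d/n)."""
    if d < 0:
        raise ValueError("deviance must be >= 0")
    return float(1.0 - np.exp(-d / n))


def backward_elimination(
    model: ScanModel,
    peaks: Sequence[Peak],
    G: GenotypeMatrix,
) -> list[Peak]:
    """Deviance-based backward elimination over peak representatives.

    The full ML model carries all surviving peak representatives as fixed
    marker effects beside X and the polygenic term.  Iteratively, the
    peak whose removal costs the least deviance is dropped while its
    chi²(df = member count) upper-tail p-value is >= 0.05; the surviving
    peaks are annotated with d, p and partial R² = 1 − exp(−d/n).
    Collinear representatives are dropped up front (later peak loses).
    """
    if not peaks:
        return []
    d_eig, U = model.eig
    n = len(model.y)
    lookup = {mid: k for k, mid in enumerate(G.marker_ids)}
    S = marker_coding(G, model.coding)

    kept = []
    cols = [model.X]
    for pk in peaks:
        cand = S[:, [lookup[pk.representative_marker]]]
        trial = np.column_stack(cols + [cand])
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            warnings.warn(
                f"peak representative {pk.representative_marker} collinear "
                "with earlier terms; dropped", stacklevel=2,
            )
            continue
        cols.append(cand)
        kept.append(pk)

    def ml_loglik(subset: list[Peak]) -> float:
        X = np.column_stack(
            [model.X] + [S[:, [lookup[p.representative_marker]]] for p in subset]
        )
        return mm.loglik_at(model.y, X, d_eig, U, method="ml")

    while kept:
        ll_full = ml_loglik(kept)
        stats_ = []
        for i, pk in enumerate(kept):
            ll_r = ml_loglik([p for j, p in enumerate(kept) if j != i])
            dev = max(0.0, 2.0 * (ll_full - ll_r))
            p_val = float(stats.chi2.sf(dev, df=len(pk.member_markers)))
            stats_.append((dev, p_val))
        worst = max(range(len(kept)), key=lambda i: stats_[i][1])
        if stats_[worst][1] >= 0.05 and len(kept) >= 1:
            kept.pop(worst)
            continue
        for pk, (dev, p_val) in zip(kept, stats_):
            pk.d = dev
            pk.p_collapse = p_val
            pk.partial_r2 = partial_r2_from_deviance(dev, n)
            pk.n = n
        break
    return kept


def dosage_effect_summary(y: np.ndarray, marker_dosages: np.ndarray) -> pd.DataFrame:
    """Mean phenotype and count per dosage class {0, 1, 2} (box-plot style
    allele-substitution summary).  Fractional dosages are rounded with a
    warning; empty classes are reported with n = 0."""
    y = np.asarray(y, dtype=float)
    dos = np.asarray(marker_dosages, dtype=float)
    if not np.allclose(dos, np.rint(dos)):
        warnings.warn("fractional dosages rounded to classes", stacklevel=2)
    dos = np.rint(dos).astype(int)
    if np.any((dos < 0) | (dos > 2)):
        raise ValueError("dosages must be in {0, 1, 2}")
    rows = []
    for c in (0, 1, 2):
        mask = dos == c
        rows.append((c, float(np.mean(y[mask])) if mask.any() else np.nan,
                     int(mask.sum())))
    return pd.DataFrame(rows, columns=["dosage", "mean", "n"])


def peaks_frame(peaks: Sequence[Peak], trait: str = "") -> pd.DataFrame:
    """Tidy peak table (trait, chromosome, position, LOD, effect, R²)."""
    return pd.DataFrame(
        [
            {
                "trait": trait,
                "chromosome": p.chrom,
                "position_bp": p.position,
                "marker_id": p.representative_marker,
                "n_members": len(p.member_markers),
                "LOD": p.lod,
                "effect": p.effect,
                "deviance": p.d,
                "p_value": p.p_collapse,
                "partial_r2": p.partial_r2,
            }
            for p in peaks
        ]
    )
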