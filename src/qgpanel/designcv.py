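"""Determinants of predictive ability: marker density, relatedness, size.

Three cross-validation experiment families, each summarised by the same
asymptotic-exponential curve used for LD decay:

* **density** — thin the marker set to a grid of window sizes, rebuild the
  relationship matrix, re-run masking cross-validation; ability is fit
  against the *realized* marker count.
* **relatedness** — start from the most genetically distant sub-group of
  accessions (k-means on marker-PC scores, farthest-centroid cluster) as
  the least-related validation population, then progressively dilute it
  with random accessions; ability is fit against a PC-space similarity
  index (mean inverse distance of each VP member to its n most similar
  training individuals).
* **size** — vary the training-population size three ways (absolute panel
  subsampling with a 10% VP, fixed VP of 60 with varying TP, fixed total
  with varying VP) and fit ability against TP size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .asymptotic import AsymptoticFit, fit_asymptotic
from .gblup import cross_validate, cross_validate_fixed
from .genotypes import GenotypeMatrix, PCAResult, thin_markers
from .kinship import KinshipMatrix, vanraden

#: thinning windows (bp) spanning 0.1 kb to 5 Mb
DEFAULT_DENSITY_GRID = (
    100, 1000, 2000, 5000, 10_000, 100_000, 250_000, 500_000,
    750_000, 1_000_000, 2_000_000, 3_000_000, 4_000_000, 5_000_000,
)

#: dilution schedule (number of VP members replaced by random accessions)
DEFAULT_DILUTION_LEVELS = (1, 3, 5, 7, 10, 13, 15, 17, 24, 27, 31, 35, 45, 50)


@dataclass
class SimilarityConfig:
    """Settings for the PC-space TP/VP similarity index."""

    n_pcs: int = 100
    n_similar: int = 40
    epsilon: float = 1e-6

    def __post_init__(self):
        if self.n_similar < 1:
            raise ValueError("n_similar must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class ExperimentResult:
    """Tidy per-replicate results plus the asymptotic summary fit."""

    data: pd.DataFrame
    fit: Optional[AsymptoticFit]
    meta: dict = field(default_factory=dict)

    def point_means(self, x: str = "grid_value") -> pd.DataFrame:
        return self.data.groupby(x, as_index=False)["ability"].mean()


def _check_grid(grid: Sequence[float]) -> np.ndarray:
    g = np.asarray(grid, dtype=float)
    if np.any(g <= 0) or np.any(np.diff(g) <= 0):
        raise ValueError("grid must be positive and strictly increasing")
    return g


def density_experiment(
    G: GenotypeMatrix,
    y: pd.Series,
    A_builder: Callable[[GenotypeMatrix], KinshipMatrix] = vanraden,
    grid: Sequence[int] = DEFAULT_DENSITY_GRID,
    vp_fraction: float = 0.10,
    n_reps: int = 100,
    seed: int = 0,
) -> ExperimentResult:
    """Predictive ability as a function of marker density.

    Windows yielding fewer than 10 markers are skipped with a warning;
    the asymptotic fit uses realized marker counts as x.  The same CV
    masks (same seed) are used at every grid point, so comparisons
    between densities are paired.
    """
    _check_grid(grid)
    frames = []
    counts = []
    for window in grid:
        Gt = thin_markers(G, int(window))
        if Gt.n_markers < 10:
            warnings.warn(
                f"window {window} bp leaves {Gt.n_markers} markers; skipped",
                stacklevel=2,
            )
            continue
        A = A_builder(Gt)
        cv = cross_validate(y, A, vp_fraction=vp_fraction, n_reps=n_reps,
                            seed=seed)
        df = cv.to_frame()
        df.insert(0, "window_bp", int(window))
        df.insert(1, "grid_value", Gt.n_markers)
        frames.append(df)
        counts.append(Gt.n_markers)
    data = pd.concat(frames, ignore_index=True)
    means = data.groupby("grid_value", as_index=False)["ability"].mean()
    fit = (
        fit_asymptotic(means["grid_value"], means["ability"])
        if len(means) >= 4 else None
    )
    return ExperimentResult(data, fit, {"grid": list(grid), "realized": counts})


def single_chrom_experiment(
    G: GenotypeMatrix,
    y: pd.Series,
    chrom: str,
    A_builder: Callable[[GenotypeMatrix], KinshipMatrix] = vanraden,
    n_random_subsets: int = 10,
    vp_fraction: float = 0.10,
    n_reps: int = 20,
    seed: int = 0,
) -> dict:
    """Ability using one chromosome's markers vs random genome-wide
    subsets of the same size; returns both abilities and their ratio."""
    on_chrom = np.flatnonzero(G.chrom == chrom)
    if len(on_chrom) < 10:
        raise ValueError(f"chromosome {chrom} has fewer than 10 markers")
    rng = np.random.default_rng(seed)
    cv_c = cross_validate(y, A_builder(G.take_markers(on_chrom)),
                          vp_fraction=vp_fraction, n_reps=n_reps, seed=seed)
    subset_means = []
    for _ in range(n_random_subsets):
        idx = np.sort(rng.choice(G.n_markers, size=len(on_chrom), replace=False))
        cv_s = cross_validate(y, A_builder(G.take_markers(idx)),
                              vp_fraction=vp_fraction, n_reps=n_reps,
                              seed=int(rng.integers(2**31)))
        subset_means.append(cv_s.mean_ability)
    random_mean = float(np.mean(subset_means))
    return {
        "chrom_ability": cv_c.mean_ability,
        "random_ability": random_mean,
        "random_abilities": subset_means,
        "ratio": cv_c.mean_ability / random_mean if random_mean else np.nan,
        "n_markers": int(len(on_chrom)),
    }


def distant_subgroup(
    pca: PCAResult,
    target_size: int,
    k: int = 8,
    seed: int = 0,
) -> np.ndarray:
    """The most genetically distant sub-group of ``target_size`` accessions.

    k-means on the PC scores; the cluster whose centroid lies farthest
    from the grand centroid is selected, trimmed (or padded from the
    next-farthest accessions) to exactly ``target_size`` by distance rank.
    """
    n = len(pca.accession_ids)
    if target_size >= n / 2:
        raise ValueError(f"target_size must be < n/2 = {n / 2:g}")
    scores = pca.scores
    if np.ptp(scores) < 1e-12:
        raise ValueError("degenerate PCA: all accessions identical")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(scores)
    grand = scores.mean(axis=0)
    cent_dist = np.linalg.norm(km.cluster_centers_ - grand, axis=1)
    far_cluster = int(np.argmax(cent_dist))
    acc_dist = np.linalg.norm(scores - grand, axis=1)
    in_cluster = np.flatnonzero(km.labels_ == far_cluster)
    ranked = in_cluster[np.argsort(-acc_dist[in_cluster])]
    if len(ranked) >= target_size:
        chosen = ranked[:target_size]
    else:
        others = np.setdiff1d(np.arange(n), in_cluster)
        pad = others[np.argsort(-acc_dist[others])][: target_size - len(ranked)]
        chosen = np.concatenate([ranked, pad])
    return pca.accession_ids[np.sort(chosen)]


def similarity_index(
    pca_scores: pd.DataFrame,
    tp_ids: Sequence,
    vp_ids: Sequence,
    scfg: SimilarityConfig = SimilarityConfig(),
) -> float:
    """Mean inverse PC-space distance between the VP and its most similar
    training individuals.

    Per VP member: mean of 1/(d + epsilon) over its ``n_similar``
    smallest Euclidean distances d to TP members in the first ``n_pcs``
    PCs; the index is the mean over VP members.
    """
    if set(tp_ids) & set(vp_ids):
        raise ValueError("TP and VP overlap")
    if scfg.n_similar > len(tp_ids):
        raise ValueError("n_similar exceeds TP size")
    use = pca_scores.iloc[:, : scfg.n_pcs]
    tp = use.loc[list(tp_ids)].to_numpy()
    vp = use.loc[list(vp_ids)].to_numpy()
    contrib = np.empty(len(vp))
    for i, v in enumerate(vp):
        d = np.linalg.norm(tp - v, axis=1)
        nearest = np.partition(d, scfg.n_similar - 1)[: scfg.n_similar]
        contrib[i] = np.mean(1.0 / (nearest + scfg.epsilon))
    return float(np.mean(contrib))


def relatedness_experiment(
    pca: PCAResult,
    y: pd.Series,
    A: KinshipMatrix,
    vp_size: int = 60,
    dilution_levels: Sequence[int] = DEFAULT_DILUTION_LEVELS,
    reps_per_level: int = 50,
    scfg: SimilarityConfig = SimilarityConfig(),
    k: int = 8,
    seed: int = 0,
) -> ExperimentResult:
    """Dilute the most distant VP with random accessions and track ability
    against the TP/VP similarity index."""
    levels = np.asarray(dilution_levels, dtype=int)
    ids = np.asarray(y.index, dtype=object)
    if vp_size + levels.max() > len(ids):
        raise ValueError("vp_size + max dilution exceeds panel size")
    base_vp = distant_subgroup(pca, vp_size, k=k, seed=seed)
    base_vp = np.asarray([a for a in base_vp if a in set(ids)], dtype=object)
    rng = np.random.default_rng(seed)
    scores = pca.scores_frame()
    rows = []
    for level in levels:
        for rep in range(reps_per_level):
            vp = base_vp.copy()
            out = rng.choice(len(vp), size=min(level, len(vp)), replace=False)
            pool = np.setdiff1d(ids, vp)
            vp[out] = rng.choice(pool, size=len(out), replace=False)
            tp = np.setdiff1d(ids, vp)
            cv = cross_validate_fixed(y, A, list(tp), list(vp))
            sim = similarity_index(scores, list(tp), list(vp), scfg)
            rows.append((int(level), rep + 1, cv.per_rep_correlations[0], sim))
    data = pd.DataFrame(rows, columns=["grid_value", "rep", "ability", "similarity"])
    by_level = data.groupby("grid_value").agg(
        ability=("ability", "mean"), similarity=("similarity", "mean")
    )
    fit = (
        fit_asymptotic(by_level["similarity"], by_level["ability"])
        if len(by_level) >= 4 and by_level["similarity"].nunique() >= 3
        else None
    )
    return ExperimentResult(data, fit, {"vp_size": vp_size,
                                        "base_vp": list(base_vp)})


def size_experiment(
    y: pd.Series,
    A: KinshipMatrix,
    mode: str = "absolute",
    grid: Sequence[int] = (),
    reps: int = 50,
    vp_fraction: float = 0.10,
    vp_size: int = 60,
    seed: int = 0,
) -> ExperimentResult:
    """Predictive ability as a function of training-population size.

    ``absolute``: subsample the panel to each grid size, VP = 10% of the
    subsample.  ``fixed_vp``: VP fixed at ``vp_size``, total varied over
    the grid.  ``fixed_total``: total fixed at the panel size, VP size
    varied over the grid.  Ability is fit against realized TP size.
    """
    if mode not in ("absolute", "fixed_vp", "fixed_total"):
        raise ValueError(f"unknown mode {mode!r}")
    ids = np.asarray(y.index, dtype=object)
    n = len(ids)
    grid = np.asarray(grid, dtype=int)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for g in grid:
        for rep in range(reps):
            if mode == "absolute":
                sub = rng.choice(ids, size=min(g, n), replace=False)
                n_vp = int(round(vp_fraction * len(sub)))
                if n_vp < 3:
                    raise ValueError(f"grid point {g} implies VP < 3")
                vp = rng.choice(sub, size=n_vp, replace=False)
                tp = np.setdiff1d(sub, vp)
            elif mode == "fixed_vp":
                if g <= vp_size:
                    raise ValueError(f"total {g} not larger than VP {vp_size}")
                sub = rng.choice(ids, size=min(g, n), replace=False)
                vp = rng.choice(sub, size=vp_size, replace=False)
                tp = np.setdiff1d(sub, vp)
            else:  # fixed_total
                if g < 3 or n - g < 2:
                    raise ValueError(f"VP size {g} invalid for panel of {n}")
                vp = rng.choice(ids, size=g, replace=False)
                tp = np.setdiff1d(ids, vp)
            cv = cross_validate_fixed(y, A, list(tp), list(vp))
            rows.append((int(g), len(tp), rep + 1, cv.per_rep_correlations[0]))
    data = pd.DataFrame(rows, columns=["grid_value", "tp_size", "rep", "ability"])
    means = data.groupby("tp_size", as_index=False)["ability"].mean()
    fit = (
        fit_asymptotic(means["tp_size"], means["ability"])
        if len(means) >= 4 else None
    )
    return ExperimentResult(data, fit, {"mode": mode, "grid": grid.tolist()})
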