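"""Marker data: container, VCF input, QC filters, thinning, LD and PCA.

The central object is :class:`GenotypeMatrix`, an accession × marker dosage
matrix (alt-allele counts in [0, 2]; fractional values from upstream
imputation are accepted) with per-marker chromosome/position/allele
metadata.  All downstream stages — kinship, association scans, genomic
prediction — consume this object.

Linkage disequilibrium is measured as r², the squared sample Pearson
correlation between dosage vectors, computed for each marker against its
nearest same-chromosome neighbours by physical distance.  The decay of
binned r² with distance is summarised by the asymptotic-exponential curve
of :mod:`qgpanel.asymptotic`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .asymptotic import AsymptoticFit, fit_asymptotic


@dataclass
class GenotypeMatrix:
    """Accession × marker dosage matrix with marker metadata.

    Invariants: marker ids unique, positions strictly increasing within
    each chromosome, no missing dosages.
    """

    accession_ids: np.ndarray
    marker_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    dosage: np.ndarray  # (n_accessions, n_markers) float
    depth_q90: Optional[np.ndarray] = None

    def __post_init__(self):
        self.accession_ids = np.asarray(self.accession_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.accession_ids), len(self.marker_ids)):
            raise ValueError("dosage shape does not match id vectors")
        if len(np.unique(self.marker_ids.astype(str))) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        if np.isnan(self.dosage).any():
            raise ValueError("missing dosages are not allowed (impute upstream)")
        if self.dosage.min() < 0 or self.dosage.max() > 2:
            raise ValueError("dosages must lie in [0, 2]")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def alt_freq(self) -> np.ndarray:
        """Observed alt-allele frequency p̂ per marker."""
        return self.dosage.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            marker_ids=self.marker_ids[index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref_allele=self.ref_allele[index],
            alt_allele=self.alt_allele[index],
            dosage=self.dosage[:, index],
            depth_q90=None if self.depth_q90 is None else self.depth_q90[index],
        )

    def take_accessions(self, ids) -> "GenotypeMatrix":
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        try:
            rows = np.array([lookup[a] for a in ids])
        except KeyError as exc:
            raise KeyError(f"unknown accession id {exc.args[0]!r}") from exc
        return replace(
            self,
            accession_ids=self.accession_ids[rows],
            dosage=self.dosage[rows, :],
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.accession_ids, other.accession_ids)
            and np.array_equal(self.marker_ids, other.marker_ids)
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref_allele, other.ref_allele)
            and np.array_equal(self.alt_allele, other.alt_allele)
            and np.allclose(self.dosage, other.dosage)
        )


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF (4.x, GT field required) into a :class:`GenotypeMatrix`.

    Dosages are alt-allele counts.  The input contract is an imputed,
    biallelic VCF: missing genotypes and multi-allelic records raise with
    the offending marker (and sample) named.  If per-genotype depth (DP)
    is present, the per-marker 90th-quantile depth is recorded.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    ids, chroms, poss, refs, alts, rows, depths = [], [], [], [], [], [], []
    has_depth = True
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {v.CHROM}:{v.POS} "
                "(filter to biallelic sites upstream)"
            )
        gts = np.asarray(v.genotypes, dtype=object)
        dos = np.empty(len(samples), dtype=float)
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                raise ValueError(
                    f"missing genotype for sample {samples[i]!r} at marker "
                    f"{v.ID or f'{v.CHROM}:{v.POS}'} (input must be imputed)"
                )
            dos[i] = a + b
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        rows.append(dos)
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        if dp is None:
            has_depth = False
        else:
            depths.append(float(np.quantile(dp.astype(float).ravel(), 0.9)))
    if not ids:
        raise ValueError(f"no variant records in {path}")
    return GenotypeMatrix(
        accession_ids=samples,
        marker_ids=np.asarray(ids, dtype=object),
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref_allele=np.asarray(refs, dtype=object),
        alt_allele=np.asarray(alts, dtype=object),
        dosage=np.column_stack(rows) if rows else np.empty((len(samples), 0)),
        depth_q90=np.asarray(depths) if has_depth else None,
    )


def filter_markers(
    G: GenotypeMatrix,
    maf_min: float = 0.05,
    depth_q90_min: float = 10.0,
    depth_q90_max: float = 500.0,
    biallelic_only: bool = True,
) -> GenotypeMatrix:
    """Marker QC: drop markers with MAF < ``maf_min``, 90th-quantile depth
    below/above the bounds, and (if requested) non-biallelic markers.

    MAF exactly equal to ``maf_min`` is retained (the filter removes
    strictly smaller values).  Depth filters are skipped with a warning
    when the matrix carries no depth information.  The accession set is
    never changed.
    """
    if not (0.0 <= maf_min < 0.5):
        raise ValueError(f"maf_min must be in [0, 0.5), got {maf_min}")
    keep = G.maf() >= maf_min
    if G.depth_q90 is not None:
        keep &= (G.depth_q90 >= depth_q90_min) & (G.depth_q90 <= depth_q90_max)
    elif depth_q90_min is not None or depth_q90_max is not None:
        warnings.warn(
            "no per-marker depth available; depth filters skipped", stacklevel=2
        )
    if biallelic_only:
        # the container is biallelic by construction; guard degenerate alleles
        keep &= np.array(
            [a not in (None, ".", "") for a in G.alt_allele], dtype=bool
        )
    return G.take_markers(np.flatnonzero(keep))


def thin_markers(G: GenotypeMatrix, window_bp: int) -> GenotypeMatrix:
    """Thin to at most one marker per non-overlapping window per chromosome.

    Windows are half-open, anchored at coordinate 0: [k·w, (k+1)·w).
    Within a window the marker with the highest MAF is kept (ties broken
    by smaller position), which is deterministic and favours informative
    markers.
    """
    if window_bp < 1:
        raise ValueError(f"window_bp must be >= 1, got {window_bp}")
    maf = G.maf()
    df = pd.DataFrame(
        {
            "idx": np.arange(G.n_markers),
            "chrom": G.chrom.astype(str),
            "win": G.pos // window_bp,
            "maf": maf,
            "pos": G.pos,
        }
    )
    df = df.sort_values(["chrom", "win", "maf", "pos"], ascending=[True, True, False, True])
    keep = df.groupby(["chrom", "win"], sort=False).head(1)["idx"].to_numpy()
    keep.sort()
    return G.take_markers(keep)


def _standardized(dosage: np.ndarray) -> np.ndarray:
    """Column-centred, unit-norm dosage; constant columns become zero."""
    X = dosage - dosage.mean(axis=0)
    norm = np.linalg.norm(X, axis=0)
    norm[norm == 0] = 1.0
    return X / norm


def _neighbor_pairs(pos: np.ndarray, n_neighbors: int) -> np.ndarray:
    """Unordered (i, j) index pairs linking each marker to its
    ``n_neighbors`` nearest neighbours by |Δpos| (local indices)."""
    m = len(pos)
    pairs = set()
    for i in range(m):
        d = np.abs(pos - pos[i])
        d[i] = np.iinfo(np.int64).max
        k = min(n_neighbors, m - 1)
        nn = np.argpartition(d, k - 1)[:k]
        for j in nn:
            pairs.add((min(i, j), max(i, j)))
    return np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)


def pairwise_ld(G: GenotypeMatrix, n_neighbors: int = 100) -> pd.DataFrame:
    """r² between each marker and its nearest same-chromosome neighbours.

    Returns a tidy frame (marker_i, marker_j, chrom, distance_bp, r2) with
    each unordered pair emitted once.  Chromosomes with a single marker
    contribute no pairs.
    """
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")
    Xs = _standardized(G.dosage)
    out = []
    for c in pd.unique(G.chrom):
        idx = np.flatnonzero(G.chrom == c)
        if len(idx) < 2:
            continue
        pairs = _neighbor_pairs(G.pos[idx], n_neighbors)
        gi, gj = idx[pairs[:, 0]], idx[pairs[:, 1]]
        r2 = np.empty(len(gi))
        for s in range(0, len(gi), 100_000):
            e = s + 100_000
            r2[s:e] = np.einsum("ij,ij->j", Xs[:, gi[s:e]], Xs[:, gj[s:e]]) ** 2
        out.append(
            pd.DataFrame(
                {
                    "marker_i": G.marker_ids[gi],
                    "marker_j": G.marker_ids[gj],
                    "chrom": np.repeat(c, len(gi)),
                    "distance_bp": G.pos[gj] - G.pos[gi],
                    "r2": np.clip(r2, 0.0, 1.0),
                }
            )
        )
    cols = ["marker_i", "marker_j", "chrom", "distance_bp", "r2"]
    if not out:
        return pd.DataFrame(columns=cols)
    res = pd.concat(out, ignore_index=True)
    res["distance_bp"] = np.abs(res["distance_bp"]).astype(np.int64)
    return res


@dataclass
class DecayFit:
    """LD decay curve LD(x) = yf + (y0 − yf)·exp(−exp(log_alpha)·x)."""

    y0: float
    yf: float
    log_alpha: float
    bin_edges: np.ndarray = field(repr=False)
    bin_means: np.ndarray = field(repr=False)
    bin_mids: np.ndarray = field(repr=False)
    residual_sse: float = 0.0

    def __call__(self, x):
        from .asymptotic import asymp_curve

        return asymp_curve(x, self.y0, self.yf, self.log_alpha)


def default_ld_bins(max_bp: float, bin_width_bp: int = 100,
                    linear_limit_bp: int = 10_000, n_log_bins: int = 30) -> np.ndarray:
    """Linear bins of ``bin_width_bp`` up to ``linear_limit_bp``, then
    log-spaced bins out to the neighbour horizon."""
    edges = np.arange(0, min(linear_limit_bp, max_bp) + bin_width_bp, bin_width_bp, dtype=float)
    if max_bp > linear_limit_bp:
        log_edges = np.geomspace(linear_limit_bp, max_bp, n_log_bins + 1)[1:]
        edges = np.concatenate([edges, log_edges])
    return np.unique(edges)


def fit_ld_decay(pairs: pd.DataFrame, bin_width_bp: int = 100,
                 bin_edges: Optional[np.ndarray] = None) -> DecayFit:
    """Bin pairwise r² by distance and fit the asymptotic decay curve to
    the bin means at the bin midpoints.  Requires >= 3 non-empty bins."""
    d = pairs["distance_bp"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    if bin_edges is None:
        bin_edges = default_ld_bins(d.max(), bin_width_bp=bin_width_bp)
    bin_edges = np.asarray(bin_edges, dtype=float)
    which = np.digitize(d, bin_edges[1:-1])
    n_bins = len(bin_edges) - 1
    sums = np.bincount(which, weights=r2, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    nonempty = counts > 0
    if nonempty.sum() < 3:
        raise ValueError(f"need >= 3 non-empty bins, got {int(nonempty.sum())}")
    mids = 0.5 * (bin_edges[:-1] + bin_edges[1:])[nonempty]
    means = (sums[nonempty] / counts[nonempty])
    fit = fit_asymptotic(mids, means)
    return DecayFit(fit.y0, fit.yf, fit.log_alpha, bin_edges, means, mids,
                    fit.residual_sse)


def decay_fit_from_params(y0: float, yf: float, log_alpha: float) -> DecayFit:
    """Construct a :class:`DecayFit` directly from curve parameters."""
    empty = np.array([])
    return DecayFit(y0, yf, log_alpha, empty, empty, empty, 0.0)


def distance_at_r2(fit: DecayFit | AsymptoticFit, level: float) -> float:
    """Invert the decay curve: distance x at which LD(x) = ``level``.

    Closed form x = ln((y0 − yf)/(level − yf)) / exp(log_alpha); requires
    yf < level <= y0 for a decreasing curve.
    """
    y0, yf, la = fit.y0, fit.yf, fit.log_alpha
    if not (yf < level <= y0):
        raise ValueError(
            f"level must lie in (yf, y0] = ({yf:.4g}, {y0:.4g}], got {level}"
        )
    return float(np.log((y0 - yf) / (level - yf)) / np.exp(la))


def sliding_ld(G: GenotypeMatrix, thin_window_bp: int = 1000,
               n_neighbors: int = 100) -> pd.DataFrame:
    """Mean r² of each marker with its nearest neighbours, on a distance-
    thinned marker set (one marker per ``thin_window_bp``), for
    Manhattan-style reporting.  Output ordered by (chrom, pos)."""
    Gt = thin_markers(G, thin_window_bp)
    Xs = _standardized(Gt.dosage)
    mean_r2 = np.full(Gt.n_markers, np.nan)
    for c in pd.unique(Gt.chrom):
        idx = np.flatnonzero(Gt.chrom == c)
        if len(idx) < 2:
            continue
        pos = Gt.pos[idx]
        for li, gi in enumerate(idx):
            d = np.abs(pos - pos[li])
            d[li] = np.iinfo(np.int64).max
            k = min(n_neighbors, len(idx) - 1)
            nn = idx[np.argpartition(d, k - 1)[:k]]
            mean_r2[gi] = float(np.mean((Xs[:, nn].T @ Xs[:, gi]) ** 2))
    out = pd.DataFrame(
        {
            "marker_id": Gt.marker_ids,
            "chrom": Gt.chrom.astype(str),
            "pos": Gt.pos,
            "mean_r2": mean_r2,
        }
    )
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


@dataclass
class PCAResult:
    """Scores and variance shares of PCA on the centred dosage matrix."""

    accession_ids: np.ndarray
    scores: np.ndarray  # (n_accessions, n_components)
    variance_explained: np.ndarray

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.accession_ids, columns=cols)


def marker_pca(G: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """PCA of the column-centred dosage matrix.

    ``variance_explained`` are eigenvalue shares of total marker variance
    (non-increasing, each in [0, 1]).
    """
    max_nc = min(G.n_accessions - 1, G.n_markers)
    if G.n_accessions < 2:
        raise ValueError("PCA needs >= 2 accessions")
    if n_components > max_nc:
        raise ValueError(f"n_components must be <= {max_nc}, got {n_components}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(G.dosage)
    return PCAResult(G.accession_ids.copy(), scores, pca.explained_variance_ratio_)
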