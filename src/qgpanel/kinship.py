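"""Realized relationship matrices from genome-wide markers.

The prediction matrix is the VanRaden construction

    A = Z Z' / sum_k 2 p_k q_k,

where Z is the column-centred dosage matrix (centring by 2·p̂_k with p̂
the observed panel alt-allele frequency) and the denominator scales the
diagonal to 1 + f (f the within-individual gametic correlation).  The
association-scan variant K = Z Z'/m drops the 2pq scaling; any positive
scalar on K is absorbed by the variance components of the mixed model.

An optional shrinkage flavour damps the sampling noise of A when the
marker count is modest: off-diagonal entries are shrunk toward zero
(diagonal kept) by a weight estimated from the marker-subsampling
variance of the entries, in the spirit of shrinkage covariance
estimators.  Shrinkage vanishes as the marker count grows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class KinshipMatrix:
    accession_ids: np.ndarray
    values: np.ndarray
    flavor: str  # vanraden | gwas_unscaled | shrunk
    denominator: float
    shrink_lambda: Optional[float] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.accession_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix not symmetric")
        self.values = 0.5 * (self.values + self.values.T)
        ev = np.linalg.eigvalsh(self.values)
        lo, hi = ev[0], max(ev[-1], 1e-300)
        if lo < -1e-8 * hi:
            raise ValueError(
                f"kinship matrix not PSD (min eigenvalue {lo:.3e})"
            )
        if lo < 0:
            logger.info("clipping tiny negative eigenvalues (min %.3e)", lo)
            w, V = np.linalg.eigh(self.values)
            self.values = (V * np.clip(w, 0.0, None)) @ V.T

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.accession_ids,
                            columns=self.accession_ids)

    def submatrix(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        idx = np.array([lookup[a] for a in ids])
        return self.values[np.ix_(idx, idx)]

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="accession")


def read_kinship_csv(path: str | Path, flavor: str = "vanraden") -> KinshipMatrix:
    df = pd.read_csv(path, index_col=0)
    return KinshipMatrix(np.asarray(df.index, dtype=object), df.to_numpy(),
                         flavor, np.nan)


def _centered(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    p = G.alt_freq()
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        bad = ", ".join(map(str, G.marker_ids[mono][:5]))
        raise ValueError(
            f"monomorphic markers present ({bad}...); run filter_markers first"
        )
    return G.dosage - 2.0 * p, p


def vanraden(G: GenotypeMatrix) -> KinshipMatrix:
    """A = ZZ'/Σ 2 p̂_k q̂_k with Z centred by observed frequencies."""
    if G.n_accessions < 2:
        raise ValueError("need >= 2 accessions")
    Z, p = _centered(G)
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    return KinshipMatrix(G.accession_ids.copy(), (Z @ Z.T) / denom,
                         "vanraden", denom)


def gwas_kinship(G: GenotypeMatrix) -> KinshipMatrix:
    """K = ZZ'/m — proportional to A but without the 2pq scaling; the
    scan's variance components absorb the scalar."""
    if G.n_accessions < 2:
        raise ValueError("need >= 2 accessions")
    Z, _ = _centered(G)
    m = G.n_markers
    return KinshipMatrix(G.accession_ids.copy(), (Z @ Z.T) / m,
                         "gwas_unscaled", float(m))


def shrink(G: GenotypeMatrix, n_subsets: int = 10) -> KinshipMatrix:
    """Shrunk VanRaden matrix: off-diagonals damped toward zero.

    lambda = (marker-subsampling variance of the off-diagonal entries of
    A) / (their total squared magnitude), clipped to [0, 1]; the sampling
    variance is estimated by recomputing A on ``n_subsets`` round-robin
    marker subsets.  Diagonal entries are left untouched.
    """
    A = vanraden(G)
    n = A.values.shape[0]
    n_subsets = min(n_subsets, G.n_markers)
    subs = []
    for s in range(n_subsets):
        idx = np.arange(s, G.n_markers, n_subsets)
        Gs = G.take_markers(idx)
        p = Gs.alt_freq()
        keep = (p > 0) & (p < 1)
        Gs = Gs.take_markers(np.flatnonzero(keep))
        if Gs.n_markers == 0:
            continue
        subs.append(vanraden(Gs).values)
    off = ~np.eye(n, dtype=bool)
    if len(subs) >= 2:
        stack = np.stack(subs)
        # variance of the mean of the subset estimates
        samp_var = stack.var(axis=0, ddof=1)[off].sum() / len(subs)
        total = (A.values[off] ** 2).sum()
        lam = float(np.clip(samp_var / total, 0.0, 1.0)) if total > 0 else 1.0
    else:
        lam = 0.0
    values = A.values.copy()
    values[off] *= 1.0 - lam
    return KinshipMatrix(A.accession_ids, values, "shrunk", A.denominator,
                         shrink_lambda=lam)
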