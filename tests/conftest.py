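"""Shared fixtures: small simulated panels reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from qgpanel import (
    GenotypeMatrix,
    SimConfig,
    TraitConfig,
    fit_stage1,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_panel():
    """120 accessions × 600 markers on 3 chromosomes, weak structure."""
    cfg = SimConfig(
        n_accessions=120,
        n_chromosomes=3,
        chrom_length=1_000_000,
        n_markers_per_chrom=200,
        seed=11,
    )
    return simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def small_trait(small_panel):
    """Records + truth + stage-1 fit for a mixed QTL/polygenic trait."""
    records, truth = simulate_phenotypes(
        small_panel, TraitConfig(n_qtl=2, qtl_effect_sd=0.8, seed=12)
    )
    fit = fit_stage1(records, "trait1")
    return records, truth, fit


@pytest.fixture(scope="session")
def structured_panel():
    """Panel with a clearly diverged subpopulation (last 60 accessions)."""
    cfg = SimConfig(
        n_accessions=200,
        n_chromosomes=3,
        chrom_length=1_000_000,
        n_markers_per_chrom=250,
        admixture_fraction=0.3,
        fst_like_divergence=0.4,
        seed=21,
    )
    return simulate_genotypes(cfg)


def iid_genotypes(n: int, m: int, seed: int, p_range=(0.1, 0.9)) -> GenotypeMatrix:
    """Linkage-free Hardy-Weinberg dosages (helper, not a fixture)."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(*p_range, size=m)
    dosage = rng.binomial(2, p, size=(n, m)).astype(float)
    pos = np.sort(rng.choice(10_000_000, size=m, replace=False)) + 1
    return GenotypeMatrix(
        accession_ids=np.array([f"s{i:04d}" for i in range(n)], dtype=object),
        marker_ids=np.array([f"m{j:05d}" for j in range(m)], dtype=object),
        chrom=np.repeat("chr1", m),
        pos=pos,
        ref_allele=np.repeat("A", m),
        alt_allele=np.repeat("C", m),
        dosage=dosage,
    )


def toy_matrix(dosage, pos=None, chrom=None, depth_q90=None) -> GenotypeMatrix:
    """GenotypeMatrix from a raw dosage array (helper, not a fixture)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 100
    if chrom is None:
        chrom = np.repeat("chr1", m)
    return GenotypeMatrix(
        accession_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        marker_ids=np.array([f"m{j}" for j in range(m)], dtype=object),
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos),
        ref_allele=np.repeat("A", m),
        alt_allele=np.repeat("C", m),
        dosage=dosage,
        depth_q90=depth_q90,
    )
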