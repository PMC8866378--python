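"""Synthetic diversity panels: genotypes, multi-environment phenotypes, truth.

The generator emulates the statistical structure of an outcrossing crop
diversity panel: several hundred accessions, nine chromosomes of biallelic
SNPs with rapid LD decay, weak population structure (one dominant marker
PC), and multi-environment phenotype records with unequal subsampling.

Genotypes use a founder-mosaic model: each gamete copies segments of a
small pool of founder haplotypes, switching to a random founder with
probability ``1 − exp(−recomb_rate·gap)`` between adjacent markers.  The
finite founder pool creates local allelic association that decays with
distance at a scale set by ``recomb_rate``; a fraction of accessions drawn
from a second, frequency-diverged founder pool (Balding–Nichols style)
creates the single dominant principal component.

Phenotypes follow the two-stage field-trial layout: a genetic value (few
detectable QTL plus a polygenic background over many small-effect markers)
plus a fixed environment effect, a genotype × environment draw, and
residual subsample noise, with 1–15 subsamples per genotype × environment
cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

_PHENO_COLUMNS = ["genotype_id", "environment", "replicate", "subsample", "trait", "value"]


@dataclass
class SimConfig:
    """Panel-level simulation settings (defaults emulate a ~660-accession
    outcrossing diversity panel on 9 chromosomes)."""

    n_accessions: int = 662
    n_chromosomes: int = 9
    chrom_length: int = 2_000_000
    n_markers_per_chrom: int = 600
    n_founder_haplotypes: int = 4
    recomb_rate: float = 1e-5  # per-bp crossover probability
    maf_floor: float = 0.05
    admixture_fraction: float = 0.10
    fst_like_divergence: float = 0.10
    seed: int = 0

    def __post_init__(self):
        for name in ("n_accessions", "n_chromosomes", "chrom_length", "n_markers_per_chrom"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_founder_haplotypes < 2:
            raise ValueError("n_founder_haplotypes must be >= 2")
        if self.n_markers_per_chrom > self.chrom_length:
            raise ValueError("n_markers_per_chrom exceeds chrom_length")
        for name in ("maf_floor", "admixture_fraction", "fst_like_divergence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 <= self.recomb_rate <= 1.0):
            raise ValueError("recomb_rate must be in [0, 1]")


@dataclass
class TraitConfig:
    """Trait architecture and field-trial noise settings."""

    n_qtl: int = 3
    qtl_effect_sd: float = 0.5
    polygenic_h2: float = 0.4
    gxe_var: float = 0.3
    resid_var: float = 1.0
    environments: Sequence[str] = ("loc1:rep1", "loc1:rep2", "loc2:rep1", "loc2:rep2")
    subsample_range: tuple[int, int] = (1, 15)
    trait: str = "trait1"
    seed: int = 0

    def __post_init__(self):
        if self.n_qtl < 0:
            raise ValueError("n_qtl must be >= 0")
        if not (0.0 <= self.polygenic_h2 <= 1.0):
            raise ValueError("polygenic_h2 must be in [0, 1]")
        for name in ("gxe_var", "resid_var"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.subsample_range
        if not (1 <= lo <= hi):
            raise ValueError("subsample_range must be an interval with 1 <= lo <= hi")
        if self.polygenic_h2 == 1.0 and (self.gxe_var > 0 or self.resid_var > 0):
            raise ValueError("polygenic_h2 = 1 requires gxe_var = resid_var = 0")


@dataclass
class TruthSet:
    """Ground truth for power/accuracy checks on a simulated trait."""

    true_breeding_values: pd.Series  # indexed by accession id
    qtl_markers: np.ndarray
    qtl_effects: np.ndarray
    realized_h2: float
    polygenic_markers: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))


def _balding_nichols(p: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    if fst <= 0:
        return p.copy()
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    return np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)


def _mosaic_dosage(founders: np.ndarray, pos: np.ndarray, n_acc: int,
                   recomb_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Dosage matrix for ``n_acc`` accessions (2 gametes each), copying
    segments of ``founders`` (K × m) with crossovers between markers."""
    K, m = founders.shape
    n_gam = 2 * n_acc
    gaps = np.diff(pos).astype(float)
    p_switch = 1.0 - np.exp(-recomb_rate * gaps)
    switch = np.empty((n_gam, m), dtype=bool)
    switch[:, 0] = True
    switch[:, 1:] = rng.random((n_gam, m - 1)) < p_switch if m > 1 else False
    draws = rng.integers(0, K, size=(n_gam, m))
    # index of the most recent switch point, per gamete and marker
    step = np.where(switch, np.arange(m)[None, :], 0)
    last = np.maximum.accumulate(step, axis=1)
    src = np.take_along_axis(draws, last, axis=1)
    haps = founders[src, np.arange(m)[None, :]]
    return haps[0::2] + haps[1::2]


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Simulate a founder-mosaic diversity panel.

    Deterministic under (cfg, cfg.seed).  Markers whose realized panel MAF
    falls below ``cfg.maf_floor`` have their founder alleles redrawn (the
    mosaic is kept) until the floor is respected.
    """
    rng = np.random.default_rng(cfg.seed)
    n_b = int(round(cfg.admixture_fraction * cfg.n_accessions))
    n_a = cfg.n_accessions - n_b
    acc_ids = np.array([f"acc{i + 1:04d}" for i in range(cfg.n_accessions)], dtype=object)
    bases = np.array(["A", "C", "G", "T"], dtype=object)

    all_chrom, all_pos, all_ids, all_ref, all_alt, dosage_cols = [], [], [], [], [], []
    for c in range(1, cfg.n_chromosomes + 1):
        m = cfg.n_markers_per_chrom
        pos = np.sort(rng.choice(cfg.chrom_length, size=m, replace=False)) + 1
        lo = max(cfg.maf_floor, 0.02)
        p = rng.uniform(lo, 1 - lo, size=m)
        p_div = _balding_nichols(p, cfg.fst_like_divergence, rng)
        fA = (rng.random((cfg.n_founder_haplotypes, m)) < p).astype(np.int8)
        fB = (rng.random((cfg.n_founder_haplotypes, m)) < p_div).astype(np.int8)

        # mosaic source indices are drawn once; founder alleles at markers
        # violating the MAF floor are redrawn until the panel respects it
        parts = []
        if n_a:
            parts.append(("A", n_a))
        if n_b:
            parts.append(("B", n_b))
        dos = np.zeros((cfg.n_accessions, m))
        row = 0
        blocks = []
        for pool, n_pool in parts:
            f = fA if pool == "A" else fB
            d = _mosaic_dosage(f, pos, n_pool, cfg.recomb_rate, rng)
            dos[row:row + n_pool] = d
            blocks.append((pool, row, n_pool))
            row += n_pool
        if cfg.maf_floor > 0:
            for _ in range(200):
                freq = dos.mean(axis=0) / 2.0
                bad = np.flatnonzero(np.minimum(freq, 1 - freq) < cfg.maf_floor)
                if len(bad) == 0:
                    break
                p[bad] = rng.uniform(lo, 1 - lo, size=len(bad))
                p_div[bad] = _balding_nichols(p[bad], cfg.fst_like_divergence, rng)
                fA[:, bad] = rng.random((cfg.n_founder_haplotypes, len(bad))) < p[bad]
                fB[:, bad] = rng.random((cfg.n_founder_haplotypes, len(bad))) < p_div[bad]
                for pool, start, n_pool in blocks:
                    f = fA if pool == "A" else fB
                    d = _mosaic_dosage(f[:, bad], pos[bad], n_pool,
                                       cfg.recomb_rate, rng)
                    dos[start:start + n_pool, bad] = d
            else:
                raise RuntimeError(
                    "could not satisfy maf_floor after 200 redraw rounds; "
                    "lower maf_floor or increase the founder pool"
                )
        ref = bases[rng.integers(0, 4, size=m)]
        alt = np.array(
            [bases[(list(bases).index(r) + rng.integers(1, 4)) % 4] for r in ref],
            dtype=object,
        )
        all_chrom.append(np.repeat(f"chr{c}", m))
        all_pos.append(pos)
        all_ids.append(np.array([f"chr{c}_{pp}" for pp in pos], dtype=object))
        all_ref.append(ref)
        all_alt.append(alt)
        dosage_cols.append(dos)

    return GenotypeMatrix(
        accession_ids=acc_ids,
        marker_ids=np.concatenate(all_ids),
        chrom=np.concatenate(all_chrom),
        pos=np.concatenate(all_pos),
        ref_allele=np.concatenate(all_ref),
        alt_allele=np.concatenate(all_alt),
        dosage=np.concatenate(dosage_cols, axis=1),
    )


def simulate_phenotypes(G: GenotypeMatrix, tcfg: TraitConfig) -> tuple[pd.DataFrame, TruthSet]:
    """Simulate multi-environment, unequally subsampled trait records.

    The breeding value is Σ QTL effects × dosage plus a polygenic term
    built from small effects on a random 20% of the remaining markers and
    rescaled so its variance matches the level implied by
    ``polygenic_h2`` relative to the plot-level noise
    (σ²_poly = h²/(1−h²)·(gxe_var + resid_var); h² = 1 uses unit
    variance and requires zero noise).  Each record adds a fixed
    environment effect (drawn once, centred to zero), a G×E draw and
    residual subsample noise.
    """
    if G.n_markers == 0 or G.n_accessions == 0:
        raise ValueError("empty genotype matrix")
    if tcfg.n_qtl > G.n_markers:
        raise ValueError(
            f"n_qtl = {tcfg.n_qtl} exceeds marker count {G.n_markers}"
        )
    rng = np.random.default_rng(tcfg.seed)
    n, m = G.n_accessions, G.n_markers

    qtl_idx = rng.choice(m, size=tcfg.n_qtl, replace=False) if tcfg.n_qtl else np.array([], dtype=int)
    qtl_eff = rng.normal(0.0, tcfg.qtl_effect_sd, size=tcfg.n_qtl)
    bv = G.dosage[:, qtl_idx] @ qtl_eff if tcfg.n_qtl else np.zeros(n)

    poly_idx = np.array([], dtype=int)
    if tcfg.polygenic_h2 > 0:
        remaining = np.setdiff1d(np.arange(m), qtl_idx)
        n_poly = max(1, int(round(0.2 * len(remaining))))
        poly_idx = rng.choice(remaining, size=n_poly, replace=False)
        raw = G.dosage[:, poly_idx] @ rng.normal(0.0, 1.0, size=n_poly)
        raw = raw - raw.mean()
        if tcfg.polygenic_h2 < 1.0:
            target = tcfg.polygenic_h2 / (1.0 - tcfg.polygenic_h2) * (
                tcfg.gxe_var + tcfg.resid_var
            )
        else:
            target = 1.0
        sd = raw.std()
        if sd > 0 and target > 0:
            bv = bv + raw * np.sqrt(target) / sd

    envs = list(tcfg.environments)
    env_eff = rng.normal(0.0, 1.0, size=len(envs))
    env_eff -= env_eff.mean()  # fixed effects are nuisance; centre them

    lo, hi = tcfg.subsample_range
    rows = []
    for j, env in enumerate(envs):
        n_sub = rng.integers(lo, hi + 1, size=n)
        ge = rng.normal(0.0, np.sqrt(tcfg.gxe_var), size=n)
        for i in range(n):
            eps = rng.normal(0.0, np.sqrt(tcfg.resid_var), size=n_sub[i])
            vals = bv[i] + env_eff[j] + ge[i] + eps
            for s, v in enumerate(vals, start=1):
                rows.append((G.accession_ids[i], env, j + 1, s, tcfg.trait, v))
    records = pd.DataFrame(rows, columns=_PHENO_COLUMNS)

    var_bv = float(np.var(bv))
    denom = var_bv + tcfg.gxe_var + tcfg.resid_var
    truth = TruthSet(
        true_breeding_values=pd.Series(bv, index=G.accession_ids, name=tcfg.trait),
        qtl_markers=G.marker_ids[qtl_idx],
        qtl_effects=qtl_eff,
        realized_h2=var_bv / denom if denom > 0 else 0.0,
        polygenic_markers=G.marker_ids[poly_idx],
    )
    return records, truth


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write the panel as VCF 4.2 (unphased GT; one contig per chromosome).

    Dosages must be integral — fractional (imputed) dosages cannot be
    encoded as hard genotype calls.
    """
    dos = np.rint(G.dosage).astype(int)
    if not np.allclose(G.dosage, dos):
        raise ValueError("fractional dosages cannot be written as GT calls")
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=qgpanel\n")
        for c in pd.unique(G.chrom):
            length = int(G.pos[G.chrom == c].max())
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(a) for a in G.accession_ids) + "\n")
        for k in range(G.n_markers):
            gts = "\t".join(gt_map[int(d)] for d in dos[:, k])
            fh.write(
                f"{G.chrom[k]}\t{G.pos[k]}\t{G.marker_ids[k]}\t"
                f"{G.ref_allele[k]}\t{G.alt_allele[k]}\t.\t.\t.\tGT\t{gts}\n"
            )


def write_panel(
    G: GenotypeMatrix,
    records: pd.DataFrame,
    dir_path: str | Path,
    truth: Optional[TruthSet] = None,
) -> dict[str, Path]:
    """Write panel.vcf + phenotypes.csv (+ truth.csv / qtl.csv) to a
    directory; the files round-trip through :func:`qgpanel.genotypes.read_vcf`
    and :func:`read_phenotypes`."""
    dir_path = Path(dir_path)
    try:
        dir_path.mkdir(parents=True, exist_ok=True)
        files = {"vcf": dir_path / "panel.vcf", "phenotypes": dir_path / "phenotypes.csv"}
        write_vcf(G, files["vcf"])
        out = records if len(records) else pd.DataFrame(columns=_PHENO_COLUMNS)
        out.to_csv(files["phenotypes"], index=False)
        if truth is not None:
            files["truth"] = dir_path / "truth.csv"
            truth.true_breeding_values.rename("true_bv").to_csv(
                files["truth"], index_label="accession"
            )
            files["qtl"] = dir_path / "qtl.csv"
            pd.DataFrame(
                {"marker_id": truth.qtl_markers, "effect": truth.qtl_effects}
            ).to_csv(files["qtl"], index=False)
        return files
    except OSError as exc:
        raise OSError(f"failed writing panel to {dir_path}: {exc}") from exc


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a long-format phenotype CSV (schema written by write_panel)."""
    df = pd.read_csv(path)
    missing = set(_PHENO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file {path} missing columns {sorted(missing)}")
    return df
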