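"""Config-driven orchestration: filter → means → kinship → GWAS/GBLUP →
design experiments, with tidy CSV/JSON outputs and a hashed manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import designcv, gblup, gwas, kinship, phenostage
from .config import RunConfig, validate
from .genotypes import filter_markers, marker_pca, read_vcf, thin_markers
from .simpanel import read_phenotypes

logger = logging.getLogger("qgpanel")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)


def run(config: RunConfig) -> Path:
    """Execute the requested stages in dependency order.

    Returns the run directory; any stage failure raises with the stage
    name attached.
    """
    issues = validate(config)
    if issues:
        raise ValueError("invalid config:\n  " + "\n  ".join(issues))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "setup"
    try:
        stage = "read"
        G = read_vcf(config.vcf)
        records = read_phenotypes(config.phenotypes)
        logger.info("read %d accessions x %d markers, %d phenotype records",
                    G.n_accessions, G.n_markers, len(records))

        stage = "filter"
        f = config.filter
        G = filter_markers(G, maf_min=f.maf_min, depth_q90_min=f.depth_q90_min,
                           depth_q90_max=f.depth_q90_max,
                           biallelic_only=f.biallelic_only)
        logger.info("filter: %d markers survive", G.n_markers)

        stage = "means"
        traits = list(config.traits) or list(pd.unique(records["trait"]))
        fits = {t: phenostage.fit_stage1(records, t) for t in traits}
        _write_csv(phenostage.genotype_means_frame(fits), out / "genotype_means.csv")
        for t, fit in fits.items():
            logger.info("stage1 %s: sigma2_ge=%.4g sigma2_eps=%.4g",
                        t, fit.sigma2_ge, fit.sigma2_eps)

        stage = "ld"
        from .genotypes import fit_ld_decay, pairwise_ld, sliding_ld

        pairs = pairwise_ld(G, n_neighbors=config.ld_neighbors)
        _write_csv(pairs, out / "ld_pairs.csv")
        try:
            decay = fit_ld_decay(pairs)
            _write_json(
                {"y0": decay.y0, "yf": decay.yf, "log_alpha": decay.log_alpha},
                out / "ld_decay.json",
            )
        except (ValueError, RuntimeError) as exc:
            logger.warning("LD decay fit skipped: %s", exc)
        _write_csv(sliding_ld(G), out / "sliding_ld.csv")
        pca = marker_pca(G, n_components=min(10, G.n_accessions - 1, G.n_markers))
        scores = pca.scores_frame()
        scores.insert(0, "accession", scores.index)
        _write_csv(scores, out / "pca_scores.csv")
        _write_csv(
            pd.DataFrame({"component": np.arange(1, len(pca.variance_explained) + 1),
                          "variance_explained": pca.variance_explained}),
            out / "pca_scree.csv",
        )

        if config.gwas.enabled:
            stage = "gwas"
            gcfg = config.gwas
            for t in traits:
                model = gwas.make_scan_model(fits[t].genotype_means, G,
                                             n_pcs=gcfg.n_pcs, coding=gcfg.coding)
                vc = gwas.null_reml(model)
                result = gwas.scan(model, G, vc)
                thr = gwas.permutation_threshold(model, G, n_perm=gcfg.n_perm,
                                                 alpha=gcfg.alpha, seed=gcfg.seed)
                result.threshold_lod = thr.threshold_lod
                result.n_permutations = thr.n_perm
                _write_csv(result.table.drop(columns="constant"),
                           out / f"scan_{t}.csv")
                _write_json(
                    {"trait": t, "threshold_LOD": thr.threshold_lod,
                     "n_perm": thr.n_perm, "alpha": thr.alpha, "seed": thr.seed,
                     "sigma2_G": vc.sigma2_G, "sigma2_eps": vc.sigma2_eps},
                    out / f"scan_{t}_meta.json",
                )
                peaks = gwas.call_peaks(result, gcfg.merge_window_bp)
                peaks = gwas.backward_elimination(model, peaks, G)
                _write_csv(gwas.peaks_frame(peaks, trait=t), out / f"peaks_{t}.csv")
                logger.info("gwas %s: threshold %.2f, %d peak(s)",
                            t, thr.threshold_lod, len(peaks))

        if config.prediction.enabled:
            stage = "predict"
            pcfg = config.prediction
            Gp = thin_markers(G, pcfg.thin_window_bp)
            builder = kinship.shrink if pcfg.kinship == "shrunk" else kinship.vanraden
            A = builder(Gp)
            A.write_csv(out / "kinship.csv")
            gebv_rows, cv_rows = [], []
            for t in traits:
                y = fits[t].genotype_means
                fit = gblup.fit_gblup(y, A)
                for a in A.accession_ids:
                    gebv_rows.append((a, t, fit.gebv[a], fit.pev[a],
                                      fit.reliability[a]))
                cv = gblup.cross_validate(y, A, vp_fraction=pcfg.vp_fraction,
                                          n_reps=pcfg.n_reps, seed=pcfg.seed)
                for r, ab in enumerate(cv.per_rep_correlations, start=1):
                    cv_rows.append((t, r, ab))
                _write_json(
                    {"trait": t, "mean_ability": cv.mean_ability,
                     "sd_ability": cv.sd_ability, "n_reps": cv.n_reps,
                     "vp_fraction": pcfg.vp_fraction, "seed": pcfg.seed,
                     "mean_reliability": float(fit.reliability.mean())},
                    out / f"cv_{t}_summary.json",
                )
                logger.info("gblup %s: ability %.3f", t, cv.mean_ability)
            _write_csv(pd.DataFrame(gebv_rows, columns=[
                "accession", "trait", "gebv", "pev", "reliability"]),
                out / "gebv.csv")
            _write_csv(pd.DataFrame(cv_rows, columns=["trait", "rep", "ability"]),
                       out / "cv_reps.csv")

        e = config.experiments
        if e.density or e.relatedness or e.size_modes:
            stage = "experiments"
            pcfg = config.prediction
            Gp = thin_markers(G, pcfg.thin_window_bp)
            builder = kinship.shrink if pcfg.kinship == "shrunk" else kinship.vanraden
            A = builder(Gp)
            t0 = traits[0]
            y = fits[t0].genotype_means
            if e.density:
                res = designcv.density_experiment(
                    G, y, A_builder=builder, grid=e.density_grid,
                    vp_fraction=pcfg.vp_fraction, n_reps=e.n_reps, seed=e.seed)
                _write_csv(res.data, out / "density_experiment.csv")
                if res.fit:
                    _write_json({"y0": res.fit.y0, "yf": res.fit.yf,
                                 "log_alpha": res.fit.log_alpha},
                                out / "density_fit.json")
            if e.relatedness:
                pca_full = marker_pca(
                    Gp, n_components=min(100, Gp.n_accessions - 1, Gp.n_markers))
                res = designcv.relatedness_experiment(
                    pca_full, y, A, vp_size=e.vp_size,
                    dilution_levels=e.dilution_levels,
                    reps_per_level=e.reps_per_level, seed=e.seed)
                _write_csv(res.data, out / "relatedness_experiment.csv")
                if res.fit:
                    _write_json({"y0": res.fit.y0, "yf": res.fit.yf,
                                 "log_alpha": res.fit.log_alpha},
                                out / "relatedness_fit.json")
            for mode in e.size_modes:
                res = designcv.size_experiment(
                    y, A, mode=mode, grid=e.size_grid, reps=e.size_reps,
                    vp_fraction=pcfg.vp_fraction, vp_size=e.vp_size, seed=e.seed)
                _write_csv(res.data, out / f"size_experiment_{mode}.csv")
                if res.fit:
                    _write_json({"y0": res.fit.y0, "yf": res.fit.yf,
                                 "log_alpha": res.fit.log_alpha},
                                out / f"size_fit_{mode}.json")

        stage = "manifest"
        manifest = {}
        for p in sorted(out.iterdir()):
            if p.name in ("manifest.json", "run.log") or p.is_dir():
                continue
            manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        _write_json(manifest, out / "manifest.json")
        return out
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
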