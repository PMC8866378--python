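"""Mixed-model association scan: oracles, permutations, peaks, deviance."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from qgpanel import (
    ScanModel,
    ScanResult,
    call_peaks,
    dosage_effect_summary,
    gwas_kinship,
    make_scan_model,
    null_reml,
    partial_r2_from_deviance,
    permutation_threshold,
    scan,
)
from qgpanel.gwas import backward_elimination, marker_coding
from qgpanel.kinship import KinshipMatrix

from conftest import iid_genotypes


def _identity_kinship(ids):
    return KinshipMatrix(np.asarray(ids, dtype=object), np.eye(len(ids)),
                         "gwas_unscaled", 1.0)


def _model(y, G, K=None, n_pcs=0):
    return make_scan_model(pd.Series(y, index=G.accession_ids), G,
                           n_pcs=n_pcs, K=K)


def test_scan_with_identity_kinship_equals_ols_ttest():
    G = iid_genotypes(60, 80, seed=1)
    rng = np.random.default_rng(2)
    y = G.dosage[:, 5] * 0.4 + rng.normal(0, 1, 60)
    model = _model(y, G, K=_identity_kinship(G.accession_ids))
    res = scan(model, G, null_reml(model))
    for j in (0, 5, 33):
        lr = stats.linregress(G.dosage[:, j], y)
        lod_ols = -np.log10(lr.pvalue)
        assert res.table.loc[j, "LOD"] == pytest.approx(lod_ols, abs=1e-8)
        assert res.table.loc[j, "effect"] == pytest.approx(lr.slope, abs=1e-10)


def test_scan_invariant_to_kinship_scale(small_panel, small_trait):
    _, _, fit = small_trait
    K = gwas_kinship(small_panel)
    K2 = KinshipMatrix(K.accession_ids, 2.0 * K.values, K.flavor, K.denominator)
    lods = []
    for kin in (K, K2):
        model = make_scan_model(fit.genotype_means, small_panel, K=kin)
        lods.append(scan(model, small_panel, null_reml(model)).table["LOD"])
    assert np.allclose(lods[0], lods[1], atol=1e-8)


def test_scan_affine_invariance(small_panel, small_trait):
    _, _, fit = small_trait
    model = make_scan_model(fit.genotype_means, small_panel)
    base = scan(model, small_panel, null_reml(model)).table["LOD"]
    model2 = make_scan_model(3.0 * fit.genotype_means - 2.0, small_panel)
    other = scan(model2, small_panel, null_reml(model2)).table["LOD"]
    assert np.allclose(base, other, atol=1e-8)


def test_null_scan_pvalues_uniform():
    """Permuted phenotype: pooled scan p-values pass a KS uniformity test."""
    G = iid_genotypes(80, 300, seed=3)
    rng = np.random.default_rng(4)
    y = rng.normal(0, 1, 80)
    model = _model(y, G)
    res = scan(model, G, null_reml(model))
    pvals = 10.0 ** (-res.table["LOD"].to_numpy())
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_self_association_dominates():
    G = iid_genotypes(50, 40, seed=5)
    y = (G.dosage[:, 7] - G.dosage[:, 7].mean()) / G.dosage[:, 7].std()
    model = _model(y, G, K=_identity_kinship(G.accession_ids))
    res = scan(model, G, null_reml(model))
    assert res.table["LOD"].idxmax() == 7


def test_constant_marker_flagged_not_fatal():
    G = iid_genotypes(40, 10, seed=6)
    G = dataclasses.replace(G, dosage=np.column_stack(
        [G.dosage[:, :9], np.ones(40)]))
    y = np.random.default_rng(0).normal(size=40)
    model = _model(y, G, K=_identity_kinship(G.accession_ids))
    res = scan(model, G, null_reml(model))
    assert bool(res.table.loc[9, "constant"])
    assert res.table.loc[9, "LOD"] == 0.0


def test_null_reml_recovers_heritability(small_panel):
    K = gwas_kinship(small_panel)
    d = np.diag(K.values).mean()
    rng = np.random.default_rng(7)
    L = np.linalg.cholesky(K.values + 1e-8 * np.eye(K.values.shape[0]))
    h2_hat = []
    for _ in range(10):
        g = L @ rng.normal(size=K.values.shape[0])
        g *= np.sqrt(0.5 / d)
        y = g + rng.normal(0, np.sqrt(0.5), K.values.shape[0])
        model = ScanModel(y, np.ones((len(y), 1)), K, K.accession_ids)
        vc = null_reml(model)
        h2_hat.append(vc.sigma2_G * d / (vc.sigma2_G * d + vc.sigma2_eps))
    assert 0.35 < np.mean(h2_hat) < 0.65


def test_null_reml_rejects_constant_phenotype(small_panel):
    K = gwas_kinship(small_panel)
    model = ScanModel(np.ones(small_panel.n_accessions),
                      np.ones((small_panel.n_accessions, 1)), K,
                      small_panel.accession_ids)
    with pytest.raises(ValueError, match="zero variance"):
        null_reml(model)


def test_doubling_kinship_halves_genetic_variance(small_panel, small_trait):
    _, _, fit = small_trait
    K = gwas_kinship(small_panel)
    model = make_scan_model(fit.genotype_means, small_panel, K=K)
    vc = null_reml(model)
    K2 = KinshipMatrix(K.accession_ids, 2 * K.values, K.flavor, K.denominator)
    model2 = make_scan_model(fit.genotype_means, small_panel, K=K2)
    vc2 = null_reml(model2)
    assert vc2.sigma2_G == pytest.approx(vc.sigma2_G / 2, rel=1e-3)
    assert vc2.sigma2_eps == pytest.approx(vc.sigma2_eps, rel=1e-3)


def test_p3d_close_to_per_marker_reml_on_small_instance():
    """The P3D approximation stays within 0.3 LOD of a full per-marker
    REML scan for moderate signals."""
    G = iid_genotypes(30, 50, seed=8)
    rng = np.random.default_rng(9)
    y = 0.5 * G.dosage[:, 3] + rng.normal(0, 1, 30)
    K = gwas_kinship(G)
    model = _model(y, G, K=K)
    res = scan(model, G, null_reml(model))
    from qgpanel import mm

    d, U = model.eig
    n = len(y)
    for j in range(0, 50, 7):
        X_full = np.column_stack([model.X, G.dosage[:, j]])
        if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
            continue
        vc_j, beta = mm.fit_variance_components(y, X_full, d, U, "reml")
        w = 1.0 / (d + vc_j.delta)
        Xt = U.T @ X_full
        XtWX_inv = np.linalg.inv(Xt.T @ (Xt * w[:, None]))
        se = np.sqrt(vc_j.sigma2_G * XtWX_inv[-1, -1])
        t = beta[-1] / se
        lod_full = -np.log10(2 * stats.t.sf(abs(t), n - X_full.shape[1]))
        lod_p3d = res.table.loc[j, "LOD"]
        if lod_p3d <= 10:
            assert abs(lod_p3d - lod_full) < 0.3


def test_permutation_threshold_monotone_in_alpha(small_panel, small_trait):
    _, _, fit = small_trait
    model = make_scan_model(fit.genotype_means, small_panel)
    t_strict = permutation_threshold(model, small_panel, n_perm=25,
                                     alpha=0.05, seed=1)
    t_loose = permutation_threshold(model, small_panel, n_perm=25,
                                    alpha=0.20, seed=1)
    assert np.array_equal(t_strict.max_lods, t_loose.max_lods)  # same seed
    assert t_strict.threshold_lod >= t_loose.threshold_lod
    with pytest.raises(ValueError):
        permutation_threshold(model, small_panel, n_perm=5, seed=1)


def _scan_result_from_rows(rows, threshold):
    table = pd.DataFrame(
        rows, columns=["marker_id", "chrom", "pos", "LOD", "effect"])
    table["se"] = 1.0
    table["score"] = 1.0
    table["constant"] = False
    return ScanResult(table, threshold_lod=threshold)


def test_peak_grouping_rules():
    res = _scan_result_from_rows(
        [("a", "chr1", 1_000_000, 8.0, 1.0)], threshold=5.0)
    assert len(call_peaks(res, 1_000_000)) == 1

    res = _scan_result_from_rows(
        [("a", "chr1", 1_000_000, 8.0, 1.0),
         ("b", "chr1", 11_000_000, 7.0, 1.0)], threshold=5.0)
    assert len(call_peaks(res, 1_000_000)) == 2

    res = _scan_result_from_rows(
        [("a", "chr1", 1_000_000, 6.0, 1.0),
         ("b", "chr1", 1_050_000, 9.0, 1.0),
         ("c", "chr1", 1_400_000, 7.0, 1.0),
         ("d", "chr1", 4_000_000, 3.0, 1.0)], threshold=5.0)
    peaks = call_peaks(res, 500_000)
    assert len(peaks) == 1
    assert peaks[0].representative_marker == "b"
    assert peaks[0].member_markers == ["a", "b", "c"]


def test_partial_r2_formula_and_monotonicity():
    n = 200
    assert partial_r2_from_deviance(0.0, n) == 0.0
    assert partial_r2_from_deviance(n * np.log(2), n) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        partial_r2_from_deviance(-1.0, n)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.floats(0.0, 100.0), st.floats(0.01, 100.0))
def test_partial_r2_strictly_increasing_in_deviance(d, delta):
    n = 150
    assert partial_r2_from_deviance(d + delta, n) > partial_r2_from_deviance(d, n)
    assert 0.0 <= partial_r2_from_deviance(d, n) < 1.0


def test_backward_elimination_deviance_matches_dense_ml_oracle():
    """Single-peak deviance equals twice the ML log-likelihood gap from an
    independent dense-matrix fit over (s2g, s2e)."""
    from scipy.optimize import minimize

    G = iid_genotypes(40, 30, seed=10)
    rng = np.random.default_rng(11)
    y = 0.9 * G.dosage[:, 4] + rng.normal(0, 1, 40)
    K = gwas_kinship(G)
    model = _model(y, G, K=K)
    vc = null_reml(model)
    res = scan(model, G, vc)
    res.threshold_lod = float(
        np.sort(res.table["LOD"].to_numpy())[-2]
    )  # only the top marker is "significant"
    peaks = call_peaks(res, 500_000_000)
    assert len(peaks) == 1
    done = backward_elimination(model, peaks, G)
    assert len(done) == 1

    def dense_ml(X):
        def neg_ll(theta):
            s2g, s2e = np.exp(theta)
            V = s2g * K.values + s2e * np.eye(40)
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
            r = y - X @ beta
            _, ld = np.linalg.slogdet(V)
            return 0.5 * (ld + r @ Vi @ r + 40 * np.log(2 * np.pi))
        best = min(
            (minimize(neg_ll, x0, method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12})
             for x0 in ([0.0, 0.0], [-2.0, 0.5], [0.5, -2.0])),
            key=lambda r: r.fun,
        )
        return -best.fun

    rep = done[0].representative_marker
    j = list(G.marker_ids).index(rep)
    X_full = np.column_stack([model.X, G.dosage[:, j]])
    d_oracle = 2.0 * (dense_ml(X_full) - dense_ml(model.X))
    assert done[0].d == pytest.approx(d_oracle, abs=5e-3)
    assert done[0].partial_r2 == pytest.approx(
        1 - np.exp(-d_oracle / 40), abs=1e-3)


def test_nonsignificant_peaks_dropped():
    G = iid_genotypes(60, 20, seed=12)
    rng = np.random.default_rng(13)
    y = rng.normal(0, 1, 60)  # pure noise: nothing should survive
    model = _model(y, G, K=_identity_kinship(G.accession_ids))
    res = scan(model, G, null_reml(model))
    res.threshold_lod = 0.0  # force every marker "significant"
    peaks = call_peaks(res, 10**9)
    done = backward_elimination(model, peaks, G)
    assert all(p.p_collapse < 0.05 for p in done)


def test_dominance_coding_is_heterozygosity_indicator():
    G = iid_genotypes(10, 3, seed=14)
    S = marker_coding(G, "dominance")
    assert np.array_equal(S, (G.dosage == 1).astype(float))


def test_dosage_effect_summary_hand_means():
    out = dosage_effect_summary(
        np.array([1.0, 2, 3, 4, 5, 6]), np.array([0, 0, 1, 1, 2, 2]))
    assert list(out["mean"]) == [1.5, 3.5, 5.5]
    assert out["n"].sum() == 6
    flat = dosage_effect_summary(np.ones(4), np.array([0, 1, 1, 2]))
    assert flat["mean"].nunique() == 1
    empty = dosage_effect_summary(np.array([1.0, 2.0]), np.array([0, 0]))
    assert empty.loc[empty["dosage"] == 2, "n"].item() == 0
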