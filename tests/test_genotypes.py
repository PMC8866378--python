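"""Marker QC, thinning, LD, decay fitting and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qgpanel import (
    distance_at_r2,
    filter_markers,
    fit_ld_decay,
    marker_pca,
    pairwise_ld,
    read_vcf,
    sliding_ld,
    thin_markers,
)
from qgpanel.asymptotic import asymp_curve
from qgpanel.genotypes import decay_fit_from_params

from conftest import iid_genotypes, toy_matrix

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1,length=1000>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
)


def test_read_vcf_hand_transcription(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(
        VCF_HEADER
        + "chr1\t100\tm1\tA\tC\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
        + "chr1\t200\tm2\tG\tT\t.\t.\t.\tGT\t0/1\t0/0\t0/1\n"
    )
    G = read_vcf(p)
    assert list(G.accession_ids) == ["s1", "s2", "s3"]
    assert np.allclose(G.dosage[:, 0], [0, 1, 2])
    assert np.allclose(G.dosage[:, 1], [1, 0, 1])
    assert G.ref_allele[1] == "G" and G.alt_allele[1] == "T"


def test_read_vcf_missing_genotype_names_marker_and_sample(tmp_path):
    p = tmp_path / "missing.vcf"
    p.write_text(
        VCF_HEADER + "chr1\t100\tm1\tA\tC\t.\t.\t.\tGT\t0/0\t./.\t1/1\n"
    )
    with pytest.raises(ValueError, match="s2.*m1|m1.*s2"):
        read_vcf(p)


def test_filter_markers_maf_boundary():
    """MAF exactly at the threshold survives; strictly below is removed."""
    n = 100
    cols = []
    for maf in (0.01, 0.04, 0.05, 0.20, 0.50):
        col = np.zeros(n)
        col[: int(round(2 * maf * n))] = 1.0  # alt count as het calls
        cols.append(col)
    G = toy_matrix(np.column_stack(cols))
    out = filter_markers(G, maf_min=0.05)
    assert out.n_markers == 3
    assert set(out.marker_ids) == {"m2", "m3", "m4"}
    assert np.array_equal(out.accession_ids, G.accession_ids)


def test_filter_markers_depth_bounds_and_warning():
    G = toy_matrix(np.tile([0.0, 1.0, 2.0, 1.0], (4, 1)).T,
                   depth_q90=np.array([5.0, 50.0, 600.0, 100.0]))
    out = filter_markers(G, maf_min=0.0)
    assert set(out.marker_ids) == {"m1", "m3"}
    G_nodepth = toy_matrix(np.tile([0.0, 1.0, 2.0, 1.0], (4, 1)).T)
    with pytest.warns(UserWarning, match="depth"):
        out2 = filter_markers(G_nodepth, maf_min=0.0)
    assert out2.n_markers == 4


def test_filter_markers_idempotent(small_panel):
    once = filter_markers(small_panel, maf_min=0.1)
    twice = filter_markers(once, maf_min=0.1)
    assert once.equals(twice)


def test_filter_rejects_bad_maf_threshold(small_panel):
    with pytest.raises(ValueError):
        filter_markers(small_panel, maf_min=0.5)


def test_thinning_window_rule_by_hand():
    # equal MAF everywhere: positions 100 and 500 share window [0,1000),
    # smaller position wins; 1500 sits alone
    G = toy_matrix(np.tile([0.0, 1.0, 2.0, 1.0], (3, 1)).T,
                   pos=np.array([100, 500, 1500]))
    out = thin_markers(G, 1000)
    assert list(out.pos) == [100, 1500]
    # higher-MAF marker wins inside a window
    dos = np.column_stack([[0, 0, 0, 2.0], [0, 1, 1, 2.0]])
    G2 = toy_matrix(dos, pos=np.array([100, 500]))
    assert list(thin_markers(G2, 1000).pos) == [500]


def test_thinning_degenerate_windows(small_panel):
    one_per_chrom = thin_markers(small_panel, 10**9)
    assert one_per_chrom.n_markers == len(pd.unique(small_panel.chrom))
    single = toy_matrix(np.array([[0.0], [2.0]]))
    assert thin_markers(single, 10).equals(single)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(window=st.integers(min_value=1, max_value=2_000_000))
def test_thinning_density_never_exceeds_one_per_window(window):
    G = iid_genotypes(10, 80, seed=4)
    out = thin_markers(G, window)
    for c in pd.unique(out.chrom):
        wins = out.pos[out.chrom == c] // window
        assert len(np.unique(wins)) == len(wins)


def test_pairwise_ld_perfect_and_hand_value():
    x = np.array([0, 0, 1, 1, 2, 2], dtype=float)
    y = np.array([0, 1, 1, 1, 2, 1], dtype=float)
    G = toy_matrix(np.column_stack([x, x, 2 - x, y]),
                   pos=np.array([10, 20, 30, 40]))
    pairs = pairwise_ld(G, n_neighbors=3).set_index(["marker_i", "marker_j"])
    assert pairs.loc[("m0", "m1"), "r2"] == pytest.approx(1.0)
    assert pairs.loc[("m0", "m2"), "r2"] == pytest.approx(1.0)  # x vs 2−x
    assert pairs.loc[("m0", "m3"), "r2"] == pytest.approx(0.5)  # hand Pearson²


def test_pairwise_ld_invariant_to_allele_relabeling(small_panel):
    G = small_panel.take_markers(np.arange(40))
    flipped = toy_matrix(2.0 - G.dosage, pos=G.pos, chrom=G.chrom)
    a = pairwise_ld(G, n_neighbors=10)["r2"].to_numpy()
    b = pairwise_ld(flipped, n_neighbors=10)["r2"].to_numpy()
    assert np.allclose(a, b, atol=1e-10)


def test_single_marker_chromosome_contributes_no_pairs():
    G = toy_matrix(np.array([[0.0, 1.0], [2.0, 1.0], [1.0, 0.0]]),
                   pos=np.array([100, 100]), chrom=np.array(["c1", "c2"]))
    assert len(pairwise_ld(G, n_neighbors=5)) == 0


def _pairs_on_curve(y0, yf, log_alpha, mids):
    return pd.DataFrame({
        "marker_i": [f"a{i}" for i in range(len(mids))],
        "marker_j": [f"b{i}" for i in range(len(mids))],
        "chrom": "chr1",
        "distance_bp": mids,
        "r2": asymp_curve(mids, y0, yf, log_alpha),
    })


def test_ld_decay_fit_recovers_noiseless_parameters():
    mids = np.arange(50, 20_000, 100)
    pairs = _pairs_on_curve(0.4, 0.05, -8.0, mids)
    fit = fit_ld_decay(pairs, bin_edges=np.arange(0, 20_001, 100))
    assert fit.y0 == pytest.approx(0.4, abs=1e-6)
    assert fit.yf == pytest.approx(0.05, abs=1e-6)
    assert fit.log_alpha == pytest.approx(-8.0, abs=1e-6)


def test_ld_decay_fit_flat_data():
    mids = np.arange(50, 5000, 100)
    pairs = _pairs_on_curve(0.1, 0.1, -5.0, mids)
    fit = fit_ld_decay(pairs, bin_edges=np.arange(0, 5001, 100))
    assert fit.y0 == pytest.approx(0.1, abs=1e-8)
    assert fit.yf == pytest.approx(0.1, abs=1e-8)


def test_ld_decay_fit_with_noise_recovers_within_tolerance():
    mids = np.arange(50, 20_000, 100).astype(float)
    for seed in range(5):
        rng = np.random.default_rng(seed)
        pairs = _pairs_on_curve(0.4, 0.05, -8.0, mids)
        pairs["r2"] = np.clip(
            pairs["r2"] + rng.normal(0, 0.005, len(pairs)), 0, 1
        )
        fit = fit_ld_decay(pairs, bin_edges=np.arange(0, 20_001, 100))
        assert fit.y0 == pytest.approx(0.4, abs=0.05)
        assert fit.yf == pytest.approx(0.05, abs=0.02)


def test_ld_decay_needs_three_bins():
    pairs = _pairs_on_curve(0.4, 0.05, -8.0, np.array([50, 150]))
    with pytest.raises(ValueError, match="3 non-empty bins"):
        fit_ld_decay(pairs, bin_edges=np.array([0.0, 100.0, 200.0]))


def test_distance_at_r2_closed_form_and_inverse():
    fit = decay_fit_from_params(0.4, 0.05, -8.0)
    expected = np.log((0.4 - 0.05) / (0.2 - 0.05)) / np.exp(-8.0)
    x = distance_at_r2(fit, 0.2)
    assert x == pytest.approx(expected, rel=1e-12)
    assert fit(x) == pytest.approx(0.2, abs=1e-10)
    assert distance_at_r2(fit, 0.4) == pytest.approx(0.0, abs=1e-12)
    for bad in (0.05, 0.5, 0.01):
        with pytest.raises(ValueError, match="level"):
            distance_at_r2(fit, bad)


def test_sliding_ld_duplicated_columns_and_length():
    col = np.array([0, 1, 2, 1, 0, 2.0])
    G = toy_matrix(np.tile(col, (5, 1)).T,
                   pos=np.array([1000, 2500, 4000, 5500, 7000]))
    out = sliding_ld(G, thin_window_bp=1000, n_neighbors=4)
    assert len(out) == 5
    assert np.allclose(out["mean_r2"], 1.0)


def test_sliding_ld_null_expectation_band():
    """Independent markers: mean r² near its null expectation 1/(n−1)."""
    G = iid_genotypes(100, 200, seed=8)
    out = sliding_ld(G, thin_window_bp=1, n_neighbors=50)
    grand = out["mean_r2"].mean()
    assert 0.5 / 99 < grand < 2.0 / 99


def test_marker_pca_separates_planted_subpopulations(structured_panel):
    from sklearn.metrics import silhouette_score

    res = marker_pca(structured_panel, 4)
    labels = np.r_[np.zeros(140), np.ones(60)]
    assert silhouette_score(res.scores[:, :1], labels) > 0
    assert np.all(np.diff(res.variance_explained) <= 1e-12)
    assert 0 < res.variance_explained.sum() <= 1.0 + 1e-9


def test_marker_pca_duplicating_accessions_keeps_directions(small_panel):
    import dataclasses

    G = small_panel
    dup = dataclasses.replace(
        G,
        accession_ids=np.array(
            [f"{a}_{k}" for k in (0, 1) for a in G.accession_ids], dtype=object
        ),
        dosage=np.vstack([G.dosage, G.dosage]),
    )
    a = marker_pca(G, 2).scores[:, 0]
    b = marker_pca(dup, 2).scores[: G.n_accessions, 0]
    assert abs(np.corrcoef(a, b)[0, 1]) == pytest.approx(1.0, abs=1e-8)
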