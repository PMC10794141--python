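"""FST estimators, f-statistics, distances, Mantel, PCA, Procrustes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rangexpand import correlations as corr
from rangexpand.containers import DistanceMatrix
from rangexpand.exceptions import AlignmentError, DegenerateInputError
from rangexpand.geo import great_circle_km

from conftest import make_manifest, make_panel, random_panel


def panel_from_freqs(rng, freqs_by_pop: dict[str, np.ndarray], n_dip: int):
    """Panel with haplotypes drawn i.i.d. Bernoulli(p) per population."""
    rows, ids, pop_of = [], [], {}
    for pop, p in freqs_by_pop.items():
        H = (rng.random((2 * n_dip, len(p))) < p).astype(np.int8)
        rows.append(H)
        for j in range(n_dip):
            sid = f"{pop}_{j}"
            ids.append(sid)
            pop_of[sid] = pop
    panel = make_panel(np.vstack(rows), sample_ids=ids)
    return panel, make_manifest(pop_of)


# ----------------------------------------------------------------------
# Hudson FST
# ----------------------------------------------------------------------

def test_fst_near_zero_without_differentiation():
    rng = np.random.default_rng(1)
    p = rng.uniform(0.2, 0.8, 800)
    panel, manifest = panel_from_freqs(rng, {"A": p, "B": p}, n_dip=30)
    dm = corr.hudson_fst_matrix(panel, manifest)
    assert abs(dm.value("A", "B")) <= 0.01


def test_fst_one_for_alternate_fixed_differences():
    """p1 = 0, p2 = 1 at every SNP plugs into the estimator as exactly 1."""
    n = 10
    A = np.zeros((2 * n, 50), dtype=np.int8)
    B = np.ones((2 * n, 50), dtype=np.int8)
    panel = make_panel(np.vstack([A, B]),
                       sample_ids=[f"A_{i}" for i in range(n)]
                       + [f"B_{i}" for i in range(n)])
    manifest = make_manifest({s: s[0] for s in panel.sample_ids})
    dm = corr.hudson_fst_matrix(panel, manifest)
    assert dm.value("A", "B") == pytest.approx(1.0)


def test_fst_invariant_to_allele_label_flips():
    rng = np.random.default_rng(4)
    panel = random_panel(rng, n_samples=12, n_var=300)
    manifest = make_manifest(
        {s: ("A" if i < 6 else "B")
         for i, s in enumerate(panel.sample_ids)})
    flipped = panel.copy()
    flip = rng.random(panel.n_variants) < 0.5
    flipped.haplotypes[:, flip] = 1 - flipped.haplotypes[:, flip]
    a = corr.hudson_fst_matrix(panel, manifest)
    b = corr.hudson_fst_matrix(flipped, manifest)
    assert np.allclose(a.values, b.values, atol=1e-12)


def simulate_island_model(rng, d=8, N=100, m=0.01, n_snp=400,
                          generations=600):
    """Wright's island model at the allele-frequency level: each deme
    receives a fraction m of its gene pool from the common migrant pool
    every generation, then drifts by binomial sampling of 2N copies."""
    p = np.full((d, n_snp), 0.5)
    for _ in range(generations):
        pool = p.mean(axis=0)
        target = (1 - m) * p + m * pool
        p = rng.binomial(2 * N, target) / (2 * N)
    return p


def test_island_model_fst_matches_theory():
    """8 demes exchanging migrants at 4Nm = 4 give mean pairwise Hudson
    FST in the neighbourhood of 1/(1 + 4Nm) = 0.2."""
    rng = np.random.default_rng(2)
    p = simulate_island_model(rng)
    panel, manifest = panel_from_freqs(
        rng, {f"D{i}": p[i] for i in range(8)}, n_dip=25)
    dm = corr.hudson_fst_matrix(panel, manifest)
    mean_fst = np.nanmean(dm.condensed())
    assert abs(mean_fst - 0.2) <= 0.3 * 0.2


def test_weir_cockerham_tracks_hudson():
    rng = np.random.default_rng(6)
    pa = rng.uniform(0.1, 0.9, 500)
    pb = np.clip(pa + rng.normal(0, 0.15, 500), 0.01, 0.99)
    panel, manifest = panel_from_freqs(rng, {"A": pa, "B": pb}, n_dip=25)
    h = corr.hudson_fst_matrix(panel, manifest).value("A", "B")
    w = corr.hudson_fst_matrix(panel, manifest,
                               estimator="weir_cockerham").value("A", "B")
    assert abs(h - w) < 0.02


# ----------------------------------------------------------------------
# f3 / f4
# ----------------------------------------------------------------------

def test_f4_identity_argument_is_exactly_zero():
    rng = np.random.default_rng(2)
    panel = random_panel(rng, n_samples=9, n_var=200)
    manifest = make_manifest(
        {s: "ABC"[i // 3] for i, s in enumerate(panel.sample_ids)})
    res = corr.f_statistic(panel, manifest, "f4", ["A", "A", "B", "C"],
                           block_snps=50)
    assert res.estimate == 0.0


def test_f4_antisymmetry_is_exact():
    rng = np.random.default_rng(3)
    panel = random_panel(rng, n_samples=12, n_var=240)
    manifest = make_manifest(
        {s: "ABCD"[i // 3] for i, s in enumerate(panel.sample_ids)})

    def f4(order):
        return corr.f_statistic(panel, manifest, "f4", order,
                                block_snps=60).estimate

    base = f4(["A", "B", "C", "D"])
    assert f4(["B", "A", "C", "D"]) == pytest.approx(-base, abs=1e-15)
    assert f4(["A", "B", "D", "C"]) == pytest.approx(-base, abs=1e-15)


def test_f3_hand_value_uncorrected():
    """a = 0, b = 1, c = 1/2 gives (c-a)(c-b) = -1/4 uncorrected."""
    A = np.zeros((8, 2), dtype=np.int8)
    B = np.ones((8, 2), dtype=np.int8)
    C = np.array([[0, 0], [1, 1]] * 4, dtype=np.int8)
    panel = make_panel(np.vstack([A, B, C]),
                       sample_ids=[f"{p}{i}" for p in "ABC"
                                   for i in range(4)])
    manifest = make_manifest({s: s[0] for s in panel.sample_ids})
    res = corr.f_statistic(panel, manifest, "f3", ["C", "A", "B"],
                           block_snps=1, corrected=False)
    assert res.estimate == pytest.approx(-0.25)


def test_f3_detects_admixture_in_generated_target(admixed_dataset):
    """A two-source admixed population has negative f3 with |Z| > 3."""
    panel, _tracts, manifest, _truth = admixed_dataset
    res = corr.f_statistic(panel, manifest, "f3",
                           ["ADM", "SRC_WCA", "SRC_OTH"], block_snps=100)
    assert res.estimate < 0
    assert res.z < -3


def test_f_statistic_requires_two_blocks():
    rng = np.random.default_rng(5)
    panel = random_panel(rng, n_samples=6, n_var=30)
    manifest = make_manifest(
        {s: "AB"[i // 3] for i, s in enumerate(panel.sample_ids)})
    with pytest.raises(DegenerateInputError):
        corr.f_statistic(panel, manifest, "f4", ["A", "B", "A", "B"],
                         block_snps=1000)


# ----------------------------------------------------------------------
# Geographic and linguistic distances
# ----------------------------------------------------------------------

def test_great_circle_closed_forms():
    assert great_circle_km((5.0, 5.0), (5.0, 5.0)) == 0.0
    assert great_circle_km((0.0, 0.0), (0.0, 1.0)) == pytest.approx(
        111.195, abs=0.01)
    assert great_circle_km((0.0, 0.0), (0.0, 180.0)) == pytest.approx(
        np.pi * 6371.0088, abs=0.1)


def test_great_circle_matrix_from_manifest():
    manifest = make_manifest({"a": "A", "b": "B"},
                             coords={"A": (0.0, 0.0), "B": (0.0, 2.0)})
    dm = corr.great_circle_matrix(manifest)
    assert dm.kind == "geographic_km"
    assert dm.value("A", "B") == pytest.approx(2 * 111.195, abs=0.02)


def test_linguistic_distance_hand_count():
    data = np.zeros((2, 10))
    data[1, :3] = 99                     # differ at 3 of 10 shared slots
    m = pd.DataFrame(data, index=["L1", "L2"])
    dm = corr.linguistic_distance_matrix(m)
    assert dm.value("L1", "L2") == pytest.approx(0.3)
    assert dm.value("L1", "L1") == 0.0


def test_linguistic_distance_symmetric_on_random_matrices():
    rng = np.random.default_rng(12)
    for _ in range(10):
        data = rng.integers(0, 4, (6, 15)).astype(float)
        data[rng.random(data.shape) < 0.2] = np.nan
        dm = corr.linguistic_distance_matrix(
            pd.DataFrame(data, index=[f"L{i}" for i in range(6)]))
        assert np.allclose(dm.values, dm.values.T, equal_nan=True)


# ----------------------------------------------------------------------
# Mantel
# ----------------------------------------------------------------------

def random_distance_matrix(rng, labels):
    n = len(labels)
    M = rng.random((n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0.0)
    return DistanceMatrix(list(labels), M, "fst")


def test_mantel_self_correlation():
    rng = np.random.default_rng(21)
    X = random_distance_matrix(rng, list("abcdefgh"))
    res = corr.mantel_test(X, X, n_perm=199, seed=0)
    assert res.r == pytest.approx(1.0)
    assert res.p == pytest.approx(1 / 200)


def test_mantel_r_equals_flat_triangle_pearson():
    rng = np.random.default_rng(22)
    labels = list("abcdefghij")
    X = random_distance_matrix(rng, labels)
    Y = random_distance_matrix(rng, labels)
    res = corr.mantel_test(X, Y, n_perm=99, seed=1)
    iu = np.triu_indices(len(labels), k=1)
    expected = stats.pearsonr(X.values[iu], Y.values[iu]).statistic
    assert res.r == pytest.approx(expected, abs=1e-12)


def test_mantel_agrees_with_reference_implementation():
    """Cross-check r and permutation p against scikit-bio's mantel."""
    skbio_dist = pytest.importorskip("skbio.stats.distance")
    rng = np.random.default_rng(23)
    labels = [f"p{i}" for i in range(12)]
    X = random_distance_matrix(rng, labels)
    base = rng.random((12, 2))
    from scipy.spatial.distance import squareform, pdist
    Y = DistanceMatrix(labels, squareform(pdist(base)), "geographic_km")
    ours = corr.mantel_test(X, Y, n_perm=999, seed=3)
    ref_r, ref_p, _ = skbio_dist.mantel(
        skbio_dist.DistanceMatrix(X.values, ids=labels),
        skbio_dist.DistanceMatrix(Y.values, ids=labels),
        method="pearson", permutations=999, alternative="two-sided")
    assert ours.r == pytest.approx(ref_r, abs=1e-12)
    assert ours.p == pytest.approx(ref_p, abs=0.05)


def test_partial_mantel_matches_manual_residual_correlation():
    rng = np.random.default_rng(24)
    labels = list("abcdefghi")
    X = random_distance_matrix(rng, labels)
    Y = random_distance_matrix(rng, labels)
    Z = random_distance_matrix(rng, labels)
    res = corr.mantel_test(X, Y, partial_on=Z, n_perm=99, seed=5)
    iu = np.triu_indices(len(labels), k=1)

    def resid(v, z):
        A = np.column_stack([np.ones_like(z), z])
        return v - A @ np.linalg.lstsq(A, v, rcond=None)[0]

    z = Z.values[iu]
    expected = stats.pearsonr(resid(X.values[iu], z),
                              resid(Y.values[iu], z)).statistic
    assert res.r == pytest.approx(expected, abs=1e-12)


def test_mantel_label_mismatch_raises():
    rng = np.random.default_rng(25)
    X = random_distance_matrix(rng, list("abcd"))
    Y = random_distance_matrix(rng, list("abce"))
    with pytest.raises(AlignmentError):
        corr.mantel_test(X, Y, n_perm=99)


def test_mantel_null_pvalues_are_uniform():
    """Under independence, permutation p-values are uniform (KS test)."""
    rng = np.random.default_rng(26)
    labels = [f"p{i}" for i in range(20)]
    pvals = []
    for k in range(200):
        X = random_distance_matrix(rng, labels)
        Y = random_distance_matrix(rng, labels)
        pvals.append(corr.mantel_test(X, Y, n_perm=199, seed=k).p)
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------

def test_pca_separates_two_duplicated_clusters():
    rng = np.random.default_rng(31)
    a = rng.integers(0, 2, 60).astype(np.int8)
    b = rng.integers(0, 2, 60).astype(np.int8)
    H = np.vstack([np.tile(a, (8, 1)), np.tile(b, (8, 1))])
    panel = make_panel(H)
    coords, _ = corr.genotype_pca(panel, n_components=2)
    pc1 = coords["PC1"].to_numpy()
    assert (pc1[:4] > 0).all() != (pc1[4:] > 0).all()
    assert np.sign(pc1[:4]).std() == 0 and np.sign(pc1[4:]).std() == 0


def test_pca_eigenvalues_match_dense_eigendecomposition():
    rng = np.random.default_rng(32)
    panel = make_panel(rng.integers(0, 2, (40, 50)).astype(np.int8))
    coords, eigvals = corr.genotype_pca(panel, n_components=5)
    # independent oracle: dense eigendecomposition of the sample covariance
    H = panel.haplotypes.astype(float)
    G = H[0::2] + H[1::2]
    p = G.mean(axis=0) / 2
    keep = (p > 0) & (p < 1)
    X = (G[:, keep] - 2 * p[keep]) / np.sqrt(p[keep] * (1 - p[keep]))
    w = np.linalg.eigvalsh(X @ X.T / (X.shape[0] - 1))[::-1]
    assert np.allclose(eigvals, w[:5], atol=1e-8)


def test_pca_sign_convention_is_deterministic():
    rng = np.random.default_rng(33)
    panel = make_panel(rng.integers(0, 2, (20, 40)).astype(np.int8))
    c1, _ = corr.genotype_pca(panel, n_components=3)
    c2, _ = corr.genotype_pca(panel, n_components=3)
    pd.testing.assert_frame_equal(c1, c2)


# ----------------------------------------------------------------------
# Procrustes
# ----------------------------------------------------------------------

def test_procrustes_recovers_applied_similarity_transform():
    rng = np.random.default_rng(41)
    A = rng.normal(size=(15, 2))
    theta = 0.7
    R0 = np.array([[np.cos(theta), np.sin(theta)],
                   [-np.sin(theta), np.cos(theta)]])
    B = 2.5 * A @ R0 + np.array([3.0, -1.0])
    res = corr.procrustes_fit(A, B, n_perm=99, seed=0)
    assert res.correlation == pytest.approx(1.0, abs=1e-9)
    assert res.scale == pytest.approx(2.5, rel=1e-9)
    assert np.allclose(res.transform(A), B, atol=1e-9)


def test_procrustes_matches_rotation_grid_search():
    """4-point toy: the SVD solution matches a brute-force search over
    rotation angle (with optimal scale/translation per angle)."""
    A = np.array([[0.0, 0.0], [1.0, 0.2], [0.3, 1.1], [-0.8, 0.4]])
    B = np.array([[0.1, -0.2], [1.4, 0.3], [0.2, 1.0], [-1.0, 0.6]])
    res = corr.procrustes_fit(A, B, n_perm=99, seed=0)
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    best = np.inf
    for theta in np.linspace(0, 2 * np.pi, 400_001):
        R = np.array([[np.cos(theta), np.sin(theta)],
                      [-np.sin(theta), np.cos(theta)]])
        M = Ac @ R
        s = (M * Bc).sum() / (M ** 2).sum()
        best = min(best, ((s * M - Bc) ** 2).sum())
    corr_grid = np.sqrt(1 - best / (Bc ** 2).sum())
    assert res.correlation == pytest.approx(corr_grid, abs=1e-4)


def test_procrustes_needs_three_points():
    with pytest.raises(DegenerateInputError):
        corr.procrustes_fit(np.zeros((2, 2)), np.ones((2, 2)))
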