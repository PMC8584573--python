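"""k-means, classical MDS and concordance with published labels."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from pcd_triage.clustering import (
    build_score_matrix,
    classical_mds,
    concordance,
    kmeans,
    mds_view_cluster,
    scatter_view_cluster,
)

# 12 points in 3 visually obvious 2-D groups (written by hand)
TWELVE_POINTS = np.array(
    [
        [0.0, 0.0], [0.3, 0.1], [0.1, 0.4], [0.25, 0.3],
        [5.0, 5.0], [5.2, 4.8], [4.9, 5.3], [5.1, 5.1],
        [10.0, 0.0], [9.8, 0.2], [10.3, 0.1], [10.1, 0.35],
    ]
)


def brute_force_min_wcss(X, k=3):
    """Exhaustive minimum-WCSS partition over all k^n labelings (oracle).

    Uses the identity WCSS = sum(x^2) - sum_c n_c ||mean_c||^2 so every
    labeling can be scored in one vectorised pass.
    """
    n = len(X)
    codes = np.arange(k**n)
    labelings = (codes[:, None] // k ** np.arange(n)) % k  # base-k digits
    total = (X**2).sum()
    explained = np.zeros(len(codes))
    complete = np.ones(len(codes), dtype=bool)
    for c in range(k):
        mask = labelings == c
        counts = mask.sum(axis=1)
        complete &= counts > 0
        sums = mask @ X  # per-labeling coordinate sums of cluster c
        with np.errstate(divide="ignore", invalid="ignore"):
            explained += np.where(counts > 0, (sums**2).sum(axis=1) / counts, 0.0)
    wcss = np.where(complete, total - explained, np.inf)
    best = int(wcss.argmin())
    return float(wcss[best]), labelings[best]


def test_kmeans_matches_exhaustive_oracle():
    """Lloyd + restarts finds the global minimum-WCSS 3-partition."""
    best_wcss, best_labels = brute_force_min_wcss(TWELVE_POINTS)
    assign = kmeans(TWELVE_POINTS, 3, n_restarts=10, seed=1)
    assert assign.wcss == pytest.approx(best_wcss, rel=1e-9)
    # same partition up to label names
    groups = {}
    for lab, true in zip(assign.labels, best_labels):
        groups.setdefault(lab, set()).add(int(true))
    assert all(len(v) == 1 for v in groups.values())


def test_kmeans_recovers_separated_blobs():
    rng = np.random.default_rng(0)
    X = np.concatenate([rng.normal(c, 0.5, size=(30, 4)) for c in (0.0, 10.0, 20.0)])
    truth = np.repeat([2, 1, 0], 30)  # ascending means; last column orders labels
    assign = kmeans(X, 3, seed=5)
    report = concordance(assign.labels, [["benign", "uncertain", "pathogenic"][t] for t in truth])
    assert report["ari"] == 1.0


def test_kmeans_degenerate_duplicate_rows():
    X = np.tile([[1.0, 2.0]], (8, 1))
    assign = kmeans(X, 3, n_restarts=3, seed=2)
    assert assign.wcss == pytest.approx(0.0, abs=1e-12)
    assert len(assign.labels) == 8


def test_kmeans_semantic_order_follows_condel():
    """Highest-Condel cluster is 'pathogenic' regardless of k-means index."""
    rng = np.random.default_rng(3)
    X = np.concatenate(
        [np.column_stack([rng.normal(m, 0.02, 20)] * 2) for m in (0.9, 0.5, 0.1)]
    )
    for seed in (1, 7, 99):
        assign = kmeans(X, 3, seed=seed)
        assert assign.labels[:20] == ["pathogenic"] * 20
        assert assign.labels[-20:] == ["benign"] * 20


def test_kmeans_input_validation():
    with pytest.raises(ValueError):
        kmeans(np.zeros((2, 3)), 3)
    with pytest.raises(ValueError, match="finite"):
        kmeans(np.array([[np.nan, 1.0]] * 5), 3)


# --- classical MDS -----------------------------------------------------------


def test_mds_isometry_on_2d_input():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(15, 2))
    emb = classical_mds(X)
    assert np.allclose(pdist(emb.coords), pdist(X), atol=1e-8)
    assert np.allclose(emb.coords.mean(0), 0.0, atol=1e-9)


def test_mds_isometry_on_2d_affine_subspace_of_5d():
    """Points on a plane in 5-D reproduce pairwise distances to 1e-8."""
    rng = np.random.default_rng(8)
    plane = rng.normal(size=(20, 2))
    basis, _ = np.linalg.qr(rng.normal(size=(5, 2)))
    X = plane @ basis.T + rng.normal(size=5)
    emb = classical_mds(X)
    assert np.allclose(pdist(emb.coords), pdist(X), atol=1e-8)


def test_mds_unit_square_distances():
    corners = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
    basis, _ = np.linalg.qr(np.random.default_rng(1).normal(size=(5, 2)))
    emb = classical_mds(corners @ basis.T)
    d = sorted(pdist(emb.coords))
    assert np.allclose(d, [1, 1, 1, 1, np.sqrt(2), np.sqrt(2)], atol=1e-8)


def test_mds_collinear_second_eigenvalue_zero():
    X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
    emb = classical_mds(X)
    assert emb.eigenvalues[1] == pytest.approx(0.0, abs=1e-8)


def test_mds_orientation_flips_against_condel():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(30, 5))
    condel = X[:, -1]
    emb = classical_mds(X, orient_against=(condel, None))
    assert np.corrcoef(emb.coords[:, 0], condel)[0, 1] <= 0


# --- cohort views ------------------------------------------------------------


def test_build_score_matrix_modes(cohort):
    m = build_score_matrix(cohort, "cadd_div33")
    assert m.X.shape == (83, 5)
    raw = build_score_matrix(cohort, "raw")
    assert np.allclose(m.X[:, 2] * 33.0, raw.X[:, 2])
    assert np.allclose(m.X[:, [0, 1, 3, 4]], raw.X[:, [0, 1, 3, 4]])
    z = build_score_matrix(cohort, "zscore")
    assert np.allclose(z.X.mean(0), 0.0, atol=1e-9)
    with pytest.raises(ValueError):
        build_score_matrix(cohort, "bogus")


def test_score_matrix_requires_three_complete_rows():
    from pcd_triage.variant_table import CohortRow, CohortTable, Consequence, ScorePanel, VariantRecord

    rec = VariantRecord("G", "NM_1.1", "c.1A>G", "p.M1V", Consequence.MISSENSE, "rs1")
    with pytest.raises(ValueError, match="at least 3"):
        build_score_matrix(CohortTable([CohortRow(rec, ScorePanel())]))


def test_wcss_non_increasing_over_seed_sweep(cohort):
    """Best-of-restarts WCSS never worsens as restarts are added."""
    m = build_score_matrix(cohort)
    prev = np.inf
    for restarts in (1, 5, 25):
        assign = kmeans(m.X, 3, n_restarts=restarts, seed=77)
        assert assign.wcss <= prev + 1e-9
        prev = assign.wcss


def test_reclustering_concordant_with_published_mds_labels(cohort):
    """Default-seed k-means on the five scores reproduces the published
    MDS-view clustering to ARI >= 0.8, with stable cluster sizes."""
    pub = {r.record.key: r.mds_label for r in cohort if r.mds_label}
    sizes = set()
    aris = []
    for seed in range(1, 21):
        assign, _, matrix = mds_view_cluster(cohort, seed=seed)
        report = concordance(dict(zip(matrix.keys, assign.colors)), pub)
        aris.append(report["ari"])
        sizes.add(tuple(sorted(assign.sizes().items())))
    assert max(aris) >= 0.8
    assert min(aris) >= 0.7  # stability across seeds
    assert len(sizes) <= 2
    assert all(dict(s)["pathogenic"] == 24 for s in sizes)


def test_mds_space_clustering_runs(cohort):
    assign, emb, matrix = mds_view_cluster(cohort, cluster_space="mds")
    assert len(assign.labels) == matrix.n == len(emb.coords)


def test_scatter_view_uses_revel_condel_rows(cohort):
    assign, keys = scatter_view_cluster(cohort)
    assert len(keys) == 83
    assert set(assign.sizes().values()) != {0}


def test_concordance_properties():
    labels = ["red"] * 5 + ["blue"] * 5 + ["green"] * 5
    assert concordance(labels, labels)["ari"] == 1.0
    permuted = ["green"] * 5 + ["red"] * 5 + ["blue"] * 5
    assert concordance(permuted, labels)["ari"] == 1.0  # permutation invariant
    report = concordance(labels, labels)
    assert sum(report["confusion"].values()) == report["n"] == 15


def test_concordance_random_labels_near_zero():
    rng = np.random.default_rng(6)
    structured = ["red"] * 28 + ["blue"] * 28 + ["green"] * 27
    aris = [
        concordance(list(rng.choice(["red", "blue", "green"], 83)), structured)["ari"]
        for _ in range(200)
    ]
    assert abs(np.mean(aris)) < 0.02


def test_concordance_key_mismatch_raises():
    with pytest.raises(KeyError, match="differ"):
        concordance({("A", "c.1A>G"): "red"}, {("B", "c.2A>G"): "red"})
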