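"""Gower dissimilarity, K-means/K-medoids, K selection, PCA, separation test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

import biopriority as bp
from conftest import make_blobs_3


def pframe(rows, columns):
    return pd.DataFrame(
        rows, columns=columns,
        index=pd.Index([f"P{i}" for i in range(len(rows))], name="patient_id"),
    )


class TestGower:
    def test_identical_records_have_zero_dissimilarity(self, toy_registry):
        cohort = pframe(
            [["high", 3.0, 1], ["high", 3.0, 1]], ["Sev3", "Wait", "Flag"]
        )
        D = bp.gower_matrix(cohort, toy_registry)
        np.testing.assert_allclose(D, 0.0)

    def test_hand_gower_on_two_numeric_variables_with_unit_range(self):
        data = pframe([[0.2, 0.4], [0.6, 0.8]], ["x", "y"])
        D = bp.gower_matrix(data, numeric_range=1.0)
        assert D.iloc[0, 1] == pytest.approx(0.4)

    def test_single_categorical_mismatch_is_maximal(self):
        from biopriority.registry import VariableRegistry, VariableSpec

        reg = VariableRegistry(
            (VariableSpec(id="C", kind="categorical", levels=("a", "b"),
                          impact_scores=(1, 2)),)
        )
        D = bp.gower_matrix(pframe([["a"], ["b"]], ["C"]), reg)
        assert D.iloc[0, 1] == 1.0

    def test_ordinal_contribution_is_rank_normalized(self, toy_registry):
        cohort = pframe(
            [["low", 0.0, 1], ["high", 0.0, 1]], ["Sev3", "Wait", "Flag"]
        )
        D = bp.gower_matrix(cohort, toy_registry)
        # Sev3 spans the full 3-level scale -> 1; Wait and Flag agree -> 0
        assert D.iloc[0, 1] == pytest.approx(1 / 3)

    def test_matrix_is_symmetric_zero_diagonal_unit_bounded(self, synthetic_cohort, registry):
        cohort, _, _ = synthetic_cohort
        D = bp.gower_matrix(cohort.head(40)[registry.ids], registry)
        arr = D.to_numpy()
        np.testing.assert_allclose(arr, arr.T)
        np.testing.assert_allclose(np.diag(arr), 0.0)
        assert arr.min() >= 0.0 and arr.max() <= 1.0 + 1e-12

    def test_zero_range_numeric_flagged_and_ignored(self):
        data = pframe([[0.5, 0.1], [0.5, 0.9]], ["const", "var"])
        with pytest.warns(UserWarning, match="zero range"):
            D = bp.gower_matrix(data)
        assert D.iloc[0, 1] == pytest.approx(0.5)  # only "var" contributes (1.0)/2


def brute_force_kmeans_optimum(X, k):
    """Exhaustive minimum of the within-cluster sum of squares on tiny data."""
    n = len(X)
    best = np.inf
    for assignment in itertools.product(range(k), repeat=n):
        groups = set(assignment)
        obj = 0.0
        for g in groups:
            pts = X[[i for i in range(n) if assignment[i] == g]]
            obj += ((pts - pts.mean(axis=0)) ** 2).sum()
        best = min(best, obj)
    return best


class TestKMeans:
    def test_three_pairs_recovered_and_objective_matches_enumeration(self):
        X = np.array(
            [[0.0, 0.0], [0.1, 0.0], [5.0, 5.0], [5.1, 5.0], [10.0, 0.0], [10.1, 0.0]]
        )
        model = bp.kmeans_cluster(X, n_clusters=3, seed=0)
        labels = model.labels_
        assert labels[0] == labels[1] and labels[2] == labels[3] and labels[4] == labels[5]
        assert len(set(labels)) == 3
        # each pair's contribution is twice the squared half-distance
        expected = 3 * 2 * (0.05**2)
        assert model.inertia_ == pytest.approx(expected)
        assert model.inertia_ == pytest.approx(brute_force_kmeans_optimum(X, 3))

    def test_objective_non_increasing_across_lloyd_iterations(self, synthetic_cohort):
        _, _, alpha = synthetic_cohort
        model = bp.kmeans_cluster(alpha.to_numpy(), n_clusters=3, seed=1)
        path = np.asarray(model.objective_path_)
        assert (np.diff(path) <= 1e-9).all()

    def test_single_cluster_centroid_is_global_mean(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, size=(30, 5))
        model = bp.kmeans_cluster(X, n_clusters=1, seed=0)
        np.testing.assert_allclose(model.cluster_centers_[0], X.mean(axis=0), atol=1e-12)
        assert model.inertia_ == pytest.approx(((X - X.mean(axis=0)) ** 2).sum())

    def test_duplicated_dataset_keeps_centroids(self):
        X, _ = make_blobs_3(seed=2)
        m1 = bp.kmeans_cluster(X, n_clusters=3, seed=0)
        m2 = bp.kmeans_cluster(np.vstack([X, X]), n_clusters=3, seed=0)
        c1 = np.array(sorted(m1.cluster_centers_.tolist()))
        c2 = np.array(sorted(m2.cluster_centers_.tolist()))
        np.testing.assert_allclose(c1, c2, atol=1e-8)

    def test_matches_sklearn_objective_on_blobs(self):
        X, _ = make_blobs_3(seed=3)
        ours = bp.kmeans_cluster(X, n_clusters=3, seed=0)
        ref = KMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
        assert ours.inertia_ == pytest.approx(ref.inertia_, rel=1e-6)
        assert adjusted_rand_score(ours.labels_, ref.labels_) == 1.0

    def test_infeasible_k_raises(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="distinct"):
            bp.kmeans_cluster(X, n_clusters=2)

    def test_deterministic_given_seed(self, synthetic_cohort):
        _, _, alpha = synthetic_cohort
        a = bp.kmeans_cluster(alpha.to_numpy(), n_clusters=3, seed=9)
        b = bp.kmeans_cluster(alpha.to_numpy(), n_clusters=3, seed=9)
        np.testing.assert_array_equal(a.labels_, b.labels_)

    def test_gower_kmedoids_recovers_blobs(self):
        X, truth = make_blobs_3(seed=4)
        D = bp.gower_matrix(pframe(X, [f"v{i}" for i in range(4)]))
        model = bp.kmeans_cluster(D.to_numpy(), n_clusters=3, mode="gower", seed=0)
        assert adjusted_rand_score(truth, model.labels_) == 1.0
        assert len(model.medoid_indices_) == 3


class TestSelectK:
    def test_three_blobs_recommend_three(self):
        X, _ = make_blobs_3(seed=5)
        sel = bp.select_k(X, k_range=range(2, 7), seed=0, n_restarts=5)
        assert sel.recommended_k == 3
        row = sel.table.set_index("K").loc[3]
        assert row["silhouette"] > 0.5

    def test_two_blobs_objective_decreasing_and_silhouette_max_at_two(self):
        rng = np.random.default_rng(6)
        X = np.vstack(
            [rng.normal(0, 0.03, (20, 3)), rng.normal(1, 0.03, (20, 3))]
        )
        sel = bp.select_k(X, k_range=range(2, 5), seed=0, n_restarts=5)
        obj = sel.table["objective"].to_numpy()
        assert (np.diff(obj) < 0).all()
        assert sel.recommended_k == 2

    def test_identical_points_are_degenerate(self):
        with pytest.raises(ValueError):
            bp.select_k(np.zeros((10, 2)), k_range=range(2, 4), seed=0)


class TestLabelClusters:
    def test_cluster_means_ordered_high_medium_low(self, scored_cohort):
        _, _, alpha, scores = scored_cohort
        model = bp.kmeans_cluster(alpha.to_numpy(), n_clusters=3, seed=0)
        labeling = bp.label_clusters(model, scores)
        means = scores.groupby(labeling.labels).mean()
        assert means["High"] > means["Medium"] > means["Low"]

    def test_single_cluster_is_medium(self):
        scores = pd.Series([0.2, 0.3], index=["a", "b"])
        model = bp.kmeans_cluster(np.array([[0.0], [1.0]]), n_clusters=1, seed=0)
        labeling = bp.label_clusters(model, scores)
        assert (labeling.labels == "Medium").all()

    def test_labels_invariant_to_cluster_index_permutation(self, scored_cohort):
        _, _, alpha, scores = scored_cohort
        model = bp.kmeans_cluster(alpha.to_numpy(), n_clusters=3, seed=0)
        base = bp.label_clusters(model, scores).labels

        class Permuted:
            labels_ = (model.labels_ + 1) % 3

        permuted = bp.label_clusters(Permuted, scores).labels
        pd.testing.assert_series_equal(base, permuted)

    def test_nonstandard_k_gets_ordinal_labels(self, scored_cohort):
        _, _, alpha, scores = scored_cohort
        model = bp.kmeans_cluster(alpha.to_numpy(), n_clusters=4, seed=0)
        labeling = bp.label_clusters(model, scores)
        assert set(labeling.labels) == {"P1", "P2", "P3", "P4"}


class TestPCA:
    def test_collinear_data_explained_entirely_by_pc1(self):
        t = np.linspace(0, 1, 10)
        alpha = pframe(np.column_stack([t, 2 * t]), ["a", "b"])
        proj = bp.pca_project(alpha)
        assert proj.explained_variance_ratio[0] == pytest.approx(1.0)
        assert proj.explained_variance_ratio[1] == pytest.approx(0.0, abs=1e-12)
        assert proj.rank_deficient

    def test_isotropic_data_splits_variance_roughly_evenly(self):
        rng = np.random.default_rng(8)
        alpha = pframe(rng.normal(0, 1, size=(4000, 2)), ["a", "b"])
        proj = bp.pca_project(alpha)
        assert proj.explained_variance_ratio[0] == pytest.approx(0.5, abs=0.05)

    def test_rank2_data_reconstructs_exactly(self):
        rng = np.random.default_rng(9)
        basis = rng.normal(size=(2, 6))
        coefs = rng.normal(size=(25, 2))
        X = coefs @ basis
        alpha = pframe(X, [f"v{i}" for i in range(6)])
        proj = bp.pca_project(alpha)
        recon = proj.coordinates.to_numpy() @ proj.loadings.to_numpy().T + X.mean(axis=0)
        np.testing.assert_allclose(recon, X, atol=1e-9)

    def test_sign_convention_largest_loading_positive(self, synthetic_cohort):
        _, _, alpha = synthetic_cohort
        proj = bp.pca_project(alpha)
        for pc in ("pc1", "pc2"):
            load = proj.loadings[pc].to_numpy()
            assert load[np.abs(load).argmax()] > 0

    def test_loadings_orthonormal(self, synthetic_cohort):
        _, _, alpha = synthetic_cohort
        L = bp.pca_project(alpha).loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(2), atol=1e-9)


class TestSeparation:
    def test_well_separated_blobs_reach_minimal_p(self):
        X, truth = make_blobs_3(seed=10)
        res = bp.separation_test(X, truth, n_permutations=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)
        D = res.mahalanobis_distances.to_numpy()
        np.testing.assert_allclose(D, D.T)
        assert (D[~np.eye(3, dtype=bool)] > 0).all()

    def test_null_labels_on_homogeneous_data_rarely_reject(self):
        rng = np.random.default_rng(11)
        rejections = 0
        for rep in range(20):
            X = rng.uniform(0, 1, size=(30, 3))
            labels = np.repeat([0, 1, 2], 10)
            res = bp.separation_test(X, labels, n_permutations=99, seed=rep)
            rejections += res.p_value <= 0.05
        assert rejections <= 2  # expect ~1 of 20 at the 5% level

    def test_coincident_centroids_have_zero_mahalanobis_distance(self):
        # two clusters built by mirroring -> identical centroids
        base = np.array([[1.0, 0.5], [-1.0, -0.5], [0.5, -1.0], [-0.5, 1.0]])
        X = np.vstack([base, base * 0.9])
        labels = np.array([0] * 4 + [1] * 4)
        res = bp.separation_test(X, labels, n_permutations=49, seed=0)
        np.testing.assert_allclose(
            res.mahalanobis_distances.to_numpy(), 0.0, atol=1e-6
        )

    def test_degenerate_inputs_rejected(self):
        X = np.random.default_rng(0).uniform(size=(10, 2))
        with pytest.raises(ValueError, match="K >= 2"):
            bp.separation_test(X, np.zeros(10, dtype=int))
        with pytest.raises(ValueError, match="at least 2"):
            bp.separation_test(X, np.array([0] * 9 + [1]))
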