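"""Featurization, embedding, clustering and supervised evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score, roc_auc_score

from t1t2map import (
    LogGrid2D,
    SpectrumMap,
    cluster_and_heatmap,
    featurize,
    metrics_from_confusion,
    reduce_dimension,
    separation_test,
    train_evaluate,
)
from t1t2map.fingerprint_classify import (
    FeatureVector,
    MODEL_NAMES,
    feature_matrix,
    rank_auc,
)


def map_from(intensity):
    intensity = np.asarray(intensity, dtype=float)
    grid = LogGrid2D(n1=intensity.shape[0], n2=intensity.shape[1])
    return SpectrumMap(intensity=intensity, grid=grid, alpha=0,
                       n_iterations=0, residual_fro=0)


def vectors(X, ids=None):
    return [FeatureVector(subject_id=ids[i] if ids else f"S{i}",
                          values=np.asarray(row, dtype=float),
                          featurizer="test")
            for i, row in enumerate(X)]


class TestFeaturize:
    def test_all_zero_map_gives_zero_vector(self):
        fv = featurize(map_from(np.zeros((40, 40))), method="grid", size=8)
        assert not np.any(fv.values)
        assert len(fv.values) == 64

    def test_identical_maps_give_identical_vectors(self, oxidized_spectrum):
        a = featurize(oxidized_spectrum)
        b = featurize(oxidized_spectrum)
        assert np.array_equal(a.values, b.values)

    def test_grid_features_are_unit_norm(self, oxygenated_spectrum):
        fv = featurize(oxygenated_spectrum)
        assert np.linalg.norm(fv.values) == pytest.approx(1.0)
        assert len(fv.values) == 32 * 32

    def test_phenotypes_are_far_apart_in_peak_feature_space(
            self, oxygenated_spectrum, oxidized_spectrum):
        a = featurize(oxygenated_spectrum, method="peaks")
        b = featurize(oxidized_spectrum, method="peaks")
        assert np.linalg.norm(a.values - b.values) > 0.5

    def test_pluggable_embedding_callable(self):
        fv = featurize(map_from(np.ones((10, 10))), method="embedding",
                       embedding=lambda F: F.sum(axis=0))
        assert len(fv.values) == 10
        with pytest.raises(ValueError):
            featurize(map_from(np.ones((4, 4))), method="embedding")

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            featurize(map_from(np.ones((4, 4))), method="cnn")

    def test_feature_matrix_rejects_mixed_featurizers(self):
        a = FeatureVector("S1", np.ones(3), "grid")
        b = FeatureVector("S2", np.ones(3), "peaks")
        with pytest.raises(ValueError):
            feature_matrix([a, b])


class TestReduceDimension:
    def test_equidistant_triple_maps_to_equilateral_triangle(self):
        # three mutually equidistant points embed exactly in the plane
        X = np.eye(3)  # pairwise distances all sqrt(2)
        coords = reduce_dimension(vectors(X), method="mds", seed=0)
        d = [np.linalg.norm(coords[i] - coords[j])
             for i, j in ((0, 1), (0, 2), (1, 2))]
        assert max(d) / min(d) == pytest.approx(1.0, abs=1e-6)

    def test_planar_configuration_is_recovered_with_zero_stress(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 2))
        coords = reduce_dimension(vectors(pts), method="mds", seed=0)
        from scipy.spatial.distance import pdist
        assert pdist(coords) == pytest.approx(pdist(pts), abs=1e-6)

    def test_fewer_than_three_subjects_rejected(self):
        with pytest.raises(ValueError):
            reduce_dimension(vectors(np.eye(2)), method="mds")

    @pytest.mark.parametrize("method", ["tsne", "isomap"])
    def test_alternative_embeddings_return_plane_coordinates(self, method):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 5))
        coords = reduce_dimension(vectors(X), method=method, seed=0)
        assert coords.shape == (10, 2)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            reduce_dimension(vectors(np.eye(3)), method="pca")


class TestClusterAndHeatmap:
    def test_duplicated_subjects_merge_first_at_zero_distance(self):
        X = np.array([[1.0, 0.0], [1.0, 0.0], [5.0, 5.0]])
        Z, order, D = cluster_and_heatmap(vectors(X))
        assert Z[0, 2] == 0.0  # first merge distance
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_three_clusters_recover_class_labels_exactly(self):
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        labels_true = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        X = np.vstack([centers[lab] for lab in labels_true])
        Z, _, _ = cluster_and_heatmap(vectors(X))
        found = hierarchy.fcluster(Z, t=3, criterion="maxclust")
        assert adjusted_rand_score(labels_true, found) == 1.0

    def test_single_subject_is_degenerate(self):
        Z, order, D = cluster_and_heatmap(vectors([[1.0, 2.0]]))
        assert Z.shape == (0, 4)
        assert order.tolist() == [0]
        assert D.shape == (1, 1)

    def test_heatmap_matrix_is_leaf_ordered(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 3))
        Z, order, D = cluster_and_heatmap(vectors(X))
        from scipy.spatial.distance import squareform, pdist
        full = squareform(pdist(X))
        assert np.allclose(D, full[np.ix_(order, order)])


class TestSeparationTest:
    def test_identical_groups_are_not_separated(self):
        values = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = ["a"] * 3 + ["b"] * 3
        t, p = separation_test(values, labels)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_separated_means_give_tiny_p(self):
        values = np.array([0.0, 0.001, -0.001, 1.0, 1.001, 0.999])
        labels = ["a"] * 3 + ["b"] * 3
        _, p = separation_test(values, labels)
        assert p < 1e-3

    def test_matches_hand_computed_welch_statistic(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 4.0, 6.0])
        t, _ = separation_test(
            np.concatenate([a, b]), ["a"] * 4 + ["b"] * 3)
        # Welch t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b)
        expected = (a.mean() - b.mean()) / math.sqrt(
            a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert t == pytest.approx(expected, rel=1e-12)

    def test_pooled_variant_matches_classic_student_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 4.0, 6.0])
        t, _ = separation_test(np.concatenate([a, b]),
                               ["a"] * 4 + ["b"] * 3, equal_var=True)
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) \
            / (len(a) + len(b) - 2)
        expected = (a.mean() - b.mean()) / math.sqrt(
            sp2 * (1 / len(a) + 1 / len(b)))
        assert t == pytest.approx(expected, rel=1e-12)

    def test_requires_two_groups_of_two(self):
        with pytest.raises(ValueError):
            separation_test(np.arange(4.0), ["a", "a", "a", "a"])
        with pytest.raises(ValueError):
            separation_test(np.arange(3.0), ["a", "a", "b"])


class TestMetrics:
    def test_hand_computed_confusion_table(self):
        m = metrics_from_confusion(tp=3, fn=1, tn=5, fp=1)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(5 / 6)
        assert m["precision"] == pytest.approx(0.75)
        assert m["ca"] == pytest.approx(0.8)
        assert m["f1"] == pytest.approx(0.75)

    @given(tp=st.integers(0, 50), tn=st.integers(0, 50),
           fp=st.integers(0, 50), fn=st.integers(0, 50))
    def test_metric_identities_hold_for_any_table(self, tp, tn, fp, fn):
        m = metrics_from_confusion(tp, tn, fp, fn)
        for value in m.values():
            assert value is None or 0.0 <= value <= 1.0
        if None not in (m["precision"], m["sensitivity"], m["f1"]):
            # F1 is the harmonic mean of precision and sensitivity
            expected = 2 / (1 / m["precision"] + 1 / m["sensitivity"])
            assert m["f1"] == pytest.approx(expected, rel=1e-12)

    def test_undefined_ratios_reported_as_missing_not_zero(self):
        m = metrics_from_confusion(tp=0, tn=5, fp=0, fn=0)
        assert m["sensitivity"] is None
        assert m["precision"] is None
        assert m["f1"] is None
        assert m["specificity"] == 1.0

    def test_rank_auc_agrees_with_roc_curve_integration(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 200)
        y[0], y[1] = 0, 1  # both classes present
        scores = rng.normal(size=200) + y  # informative with ties unlikely
        assert rank_auc(scores, y) == pytest.approx(
            roc_auc_score(y, scores), abs=1e-12)
        # midrank handling on heavily tied scores
        tied = np.round(scores)
        assert rank_auc(tied, y) == pytest.approx(
            roc_auc_score(y, tied), abs=1e-12)


class TestTrainEvaluate:
    def separable(self, n=16):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(n, 3)) * 0.1
        X[n // 2:, 0] += 5.0
        labels = ["non_disease"] * (n // 2) + ["disease"] * (n // 2)
        return X, labels

    @pytest.mark.parametrize("model", MODEL_NAMES)
    def test_perfectly_separable_features_score_perfectly(self, model):
        X, labels = self.separable()
        res = train_evaluate(X, labels, model=model, protocol="loo", seed=0)
        assert res.metrics["ca"] == 1.0
        assert res.metrics["auc"] == 1.0
        assert res.n == len(labels)

    def test_loo_is_seed_independent_for_deterministic_models(self):
        X, labels = self.separable()
        for model in ("logistic_regression", "knn", "naive_bayes"):
            a = train_evaluate(X, labels, model=model, protocol="loo",
                               seed=0)
            b = train_evaluate(X, labels, model=model, protocol="loo",
                               seed=99)
            assert a.metrics == b.metrics

    def test_uninformative_features_score_at_chance(self):
        """Random balanced labels on real features: CA hovers near 0.5."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(32, 6))
        cas = []
        for s in range(20):
            perm_rng = np.random.default_rng(s)
            labels = np.array(["disease"] * 16 + ["non_disease"] * 16)
            perm_rng.shuffle(labels)
            res = train_evaluate(X, labels, model="knn", protocol=5,
                                 seed=s)
            cas.append(res.metrics["ca"])
        assert abs(float(np.mean(cas)) - 0.5) <= 0.15

    def test_single_class_rejected(self):
        X = np.ones((6, 2))
        with pytest.raises(ValueError):
            train_evaluate(X, ["disease"] * 6, protocol="loo")

    def test_unknown_model_and_bad_k_rejected(self):
        X, labels = self.separable()
        with pytest.raises(ValueError):
            train_evaluate(X, labels, model="svm")
        with pytest.raises(ValueError):
            train_evaluate(X, labels, protocol=1)
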