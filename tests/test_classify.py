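"""Classifier correctness against independent oracles, plus the decision
layer's label contracts."""

from __future__ import annotations

import numpy as np
import pytest

from tomatovision.classify import (
    DiseaseLabel,
    FeatureVector,
    HealthLabel,
    classify_disease,
    fit_task_model,
    knn_fit,
    knn_neighbors,
    knn_predict,
    lda_fit,
    lda_predict,
    load_model,
    pca_fit,
    pca_transform,
    predict_task,
    qda_discriminants,
    qda_fit,
    qda_predict,
    save_model,
)
from tomatovision.exceptions import DataError, ParameterError, ShapeError


class TestPca:
    def test_collinear_points_give_line_direction(self, rng):
        x = rng.normal(size=200)
        data = np.column_stack([x, 2 * x])  # exactly on y = 2x
        model = pca_fit(data)
        v1 = model.components[:, 0]
        expected = np.array([1.0, 2.0]) / np.sqrt(5.0)
        assert np.allclose(np.abs(v1 @ expected), 1.0, atol=1e-12)
        assert model.eigenvalues[1] == pytest.approx(0.0, abs=1e-12)

    def test_full_rank_projection_reconstructs_centered_data(self, rng):
        data = rng.normal(size=(15, 4))
        model = pca_fit(data)
        projected = pca_transform(model, data)
        reconstructed = projected @ model.components.T + model.mean
        assert np.allclose(reconstructed, data, atol=1e-10)

    def test_eigenstructure_matches_characteristic_polynomial_oracle(self, rng):
        import sympy

        data = rng.normal(size=(10, 4))
        model = pca_fit(data)
        centered = data - data.mean(axis=0)
        cov = centered.T @ centered / (data.shape[0] - 1)
        lam = sympy.symbols("lam")
        coeffs = [float(c) for c in sympy.Matrix(cov).charpoly(lam).all_coeffs()]
        roots = sorted(np.roots(coeffs).real, reverse=True)
        assert np.allclose(model.eigenvalues, roots, atol=1e-8)
        for j in range(4):
            v = model.components[:, j]
            assert np.allclose(cov @ v, model.eigenvalues[j] * v, atol=1e-8)

    def test_trace_identity(self, rng):
        data = rng.normal(size=(40, 6)) * np.array([1, 2, 3, 4, 5, 6])
        model = pca_fit(data)
        total_var = ((data - data.mean(axis=0)) ** 2).sum() / (len(data) - 1)
        assert model.eigenvalues.sum() == pytest.approx(total_var, rel=1e-8)

    def test_mean_maps_to_origin_and_variances_match_eigenvalues(self, rng):
        data = rng.normal(size=(30, 3))
        model = pca_fit(data)
        assert np.allclose(pca_transform(model, model.mean[None, :]), 0.0, atol=1e-12)
        projected = pca_transform(model, data)
        var = projected.var(axis=0, ddof=1)
        assert np.allclose(var, model.eigenvalues, atol=1e-10)

    def test_errors(self, rng):
        with pytest.raises(DataError):
            pca_fit(rng.normal(size=(1, 3)))
        model = pca_fit(rng.normal(size=(5, 3)))
        with pytest.raises(ShapeError):
            pca_transform(model, rng.normal(size=(4, 2)))


class TestLda:
    def test_symmetric_two_class_direction(self, rng):
        a = rng.normal(size=(100, 2))
        b = rng.normal(size=(100, 2)) + 10.0
        X = np.vstack([a, b])
        y = np.array(["a"] * 100 + ["b"] * 100)
        model = lda_fit(X, y)
        w = model.scalings[:, 0]
        w = w / np.linalg.norm(w)
        assert abs(abs(w @ np.array([1, 1]) / np.sqrt(2)) - 1.0) < 0.05
        assert (lda_predict(model, X) == y).all()

    def test_single_class_errors(self, rng):
        with pytest.raises(DataError):
            lda_fit(rng.normal(size=(10, 2)), np.zeros(10))

    def test_fisher_ratio_maximal_among_random_directions(self, rng):
        X = np.vstack(
            [
                rng.normal(size=(40, 3)) + mu
                for mu in ([0, 0, 0], [3, 1, 0], [0, 2, 4])
            ]
        )
        y = np.repeat([0, 1, 2], 40)

        grand = X.mean(axis=0)
        sw = np.zeros((3, 3))
        sb = np.zeros((3, 3))
        for c in range(3):
            Xc = X[y == c]
            m = Xc.mean(axis=0)
            sw += (Xc - m).T @ (Xc - m)
            sb += len(Xc) * np.outer(m - grand, m - grand)

        def fisher(w):
            return (w @ sb @ w) / (w @ sw @ w)

        model = lda_fit(X, y)
        best = fisher(model.scalings[:, 0])
        for _ in range(1000):
            w = rng.normal(size=3)
            assert fisher(w) <= best + 1e-9

    def test_class_mean_predicts_its_class(self, rng):
        X = np.vstack([rng.normal(size=(30, 2)), rng.normal(size=(30, 2)) + 6])
        y = np.array([0] * 30 + [1] * 30)
        model = lda_fit(X, y)
        assert lda_predict(model, model.means[0][None, :])[0] == 0
        assert lda_predict(model, model.means[1][None, :])[0] == 1

    def test_exact_score_tie_goes_to_lower_class_index(self):
        from tomatovision.classify import LdaModel

        model = LdaModel(
            classes=np.array([3, 7]),
            means=np.array([[-1.0, 0.0], [1.0, 0.0]]),
            coef=np.array([[0.0, 0.0], [0.0, 0.0]]),  # both scores identical
            intercept=np.array([0.5, 0.5]),
            scalings=np.array([[1.0], [0.0]]),
            priors=np.array([0.5, 0.5]),
        )
        assert lda_predict(model, np.array([[2.0, 2.0]]))[0] == 3

    def test_held_out_accuracy_on_separated_classes(self, rng):
        def draw(n):
            return [
                rng.normal(size=(n, 4)) + mu
                for mu in ([0] * 4, [8, 0, 0, 0], [0, 8, 0, 0])
            ]

        train = draw(50)
        test = draw(40)
        X = np.vstack(train)
        y = np.repeat([0, 1, 2], 50)
        model = lda_fit(X, y)
        pred = lda_predict(model, np.vstack(test))
        truth = np.repeat([0, 1, 2], 40)
        assert (pred == truth).mean() >= 0.95

    def test_agrees_with_reference_implementation(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = np.vstack([rng.normal(size=(60, 3)), rng.normal(size=(60, 3)) + 2.5])
        y = np.array([0] * 60 + [1] * 60)
        ours = lda_predict(lda_fit(X, y), X)
        ref = LinearDiscriminantAnalysis().fit(X, y).predict(X)
        assert (ours == ref).mean() >= 0.99


class TestQda:
    def test_parameters_match_their_defining_formulas(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        model = qda_fit(X, y)
        for i, c in enumerate(model.classes):
            Xc = X[y == c]
            assert np.allclose(model.means[i], Xc.mean(axis=0))
            dev = Xc - Xc.mean(axis=0)
            assert np.allclose(model.covariances[i], dev.T @ dev / len(Xc), atol=1e-9)
            assert model.priors[i] == pytest.approx(len(Xc) / 50)

    def test_predictions_match_direct_formula_oracle(self, rng):
        X = np.vstack([rng.normal(size=(40, 3)), rng.normal(size=(40, 3)) * 2 + 1])
        y = np.array([0] * 40 + [1] * 40)
        model = qda_fit(X, y)
        queries = rng.normal(size=(25, 3)) * 2

        def oracle_label(x):
            scores = []
            for i in range(2):
                dev = x - model.means[i]
                sigma = model.covariances[i]
                val = (
                    dev @ np.linalg.inv(sigma) @ dev
                    - 2.0 * np.log(model.priors[i])
                    + np.linalg.slogdet(sigma)[1]
                )
                scores.append(val)
            return model.classes[int(np.argmin(scores))]

        pred = qda_predict(model, queries)
        for q, p in zip(queries, pred):
            assert p == oracle_label(q)

    def test_class_mean_with_equal_priors_and_covariances(self, rng):
        base = rng.normal(size=(200, 2))
        X = np.vstack([base, base + 8])  # identical covariance by construction
        y = np.array([0] * 200 + [1] * 200)
        model = qda_fit(X, y)
        assert qda_predict(model, model.means[0][None, :])[0] == 0
        assert qda_predict(model, model.means[1][None, :])[0] == 1

    def test_scale_difference_yields_closed_boundary(self, rng):
        # tight class inside a broad class: the tight-class region is bounded
        tight = rng.normal(size=(500, 2)) * 0.5
        broad = rng.normal(size=(500, 2)) * 3.0
        X = np.vstack([tight, broad])
        y = np.array([0] * 500 + [1] * 500)
        model = qda_fit(X, y)
        assert qda_predict(model, np.zeros((1, 2)))[0] == 0
        ring = np.array([[8 * np.cos(t), 8 * np.sin(t)] for t in np.linspace(0, 2 * np.pi, 16)])
        assert (qda_predict(model, ring) == 1).all()

    def test_constant_feature_still_fits_via_regularization(self, rng):
        X = rng.normal(size=(30, 3))
        X[:, 2] = 5.0  # zero variance
        y = np.array([0] * 15 + [1] * 15)
        model = qda_fit(X, y)
        assert np.isfinite(qda_discriminants(model, X)).all()

    def test_agrees_with_reference_implementation(self, rng):
        from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

        X = np.vstack([rng.normal(size=(80, 3)), rng.normal(size=(80, 3)) * 1.8 + 3])
        y = np.array([0] * 80 + [1] * 80)
        ours = qda_predict(qda_fit(X, y), X)
        ref = QuadraticDiscriminantAnalysis(store_covariance=True).fit(X, y).predict(X)
        # covariance normalization differs (1/n here vs 1/(n-1) in the
        # reference), so only near-boundary points may disagree
        assert (ours == ref).mean() >= 0.97


class TestKnn:
    def test_training_point_query_k1(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.integers(0, 3, size=20)
        model = knn_fit(X, y, k=1)
        assert (knn_predict(model, X) == y).all()

    def test_neighbor_sets_match_brute_force(self, rng):
        X = rng.normal(size=(50, 4))
        y = rng.integers(0, 2, size=50)
        queries = rng.normal(size=(10, 4))
        model = knn_fit(X, y, k=7)
        ours = knn_neighbors(model, queries)
        for q, row in zip(queries, ours):
            dist = np.linalg.norm(X - q, axis=1)
            expected = np.argsort(dist, kind="stable")[:7]
            assert np.array_equal(np.sort(row), np.sort(expected))

    def test_k2_tie_goes_to_nearer_neighbor(self):
        X = np.array([[0.0], [3.0]])
        y = np.array(["near", "far"])
        model = knn_fit(X, y, k=2)
        assert knn_predict(model, np.array([[1.0]]))[0] == "near"
        assert knn_predict(model, np.array([[2.5]]))[0] == "far"

    def test_k_equal_n_predicts_global_majority(self, rng):
        X = rng.normal(size=(21, 2))
        y = np.array([0] * 13 + [1] * 8)
        model = knn_fit(X, y, k=21)
        queries = rng.normal(size=(5, 2)) * 10
        assert (knn_predict(model, queries) == 0).all()

    def test_k_out_of_range_errors(self, rng):
        X = rng.normal(size=(5, 2))
        y = np.zeros(5)
        with pytest.raises(ParameterError):
            knn_fit(X, y, k=0)
        with pytest.raises(ParameterError):
            knn_fit(X, y, k=6)

    def test_agrees_with_reference_implementation(self, rng):
        from sklearn.neighbors import KNeighborsClassifier

        X = rng.normal(size=(60, 3))
        y = rng.integers(0, 2, size=60)
        queries = rng.normal(size=(30, 3))
        ours = knn_predict(knn_fit(X, y, k=1), queries)
        ref = KNeighborsClassifier(n_neighbors=1).fit(X, y).predict(queries)
        assert np.array_equal(ours, ref)


class TestDecisionLayer:
    def test_lda_equals_qda_under_pooled_covariance(self, rng):
        # identical class covariances: quadratic terms cancel, boundaries agree
        base = rng.normal(size=(300, 2))
        X = np.vstack([base, base + [5, 3]])
        y = np.array([0] * 300 + [1] * 300)
        lda = lda_fit(X, y)
        qda = qda_fit(X, y)
        gx, gy = np.meshgrid(np.linspace(-3, 8, 30), np.linspace(-3, 6, 30))
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        agreement = (lda_predict(lda, grid) == qda_predict(qda, grid)).mean()
        assert agreement >= 0.99

    def test_disease_guard_on_healthy_sample(self, small_feature_table):
        table = small_feature_table
        infected = table["health"] == "risky"
        model = fit_task_model(
            table["X"][infected], table["disease"][infected], task="disease"
        )
        fv = FeatureVector("s0", table["X"][0])
        from tomatovision.features import ClusterSet

        dummy = ClusterSet(
            k=4,
            label_map=np.full((2, 2), -1),
            means=np.zeros((4, 3)),
            descriptors=(),
        )
        with pytest.warns(UserWarning):
            label = classify_disease(dummy, fv, model, health=HealthLabel.HEALTHY)
        assert label == DiseaseLabel.NONE

    def test_model_round_trip_preserves_predictions(self, small_feature_table, tmp_path):
        table = small_feature_table
        for classifier in ("knn", "lda", "qda", "pca+knn"):
            model = fit_task_model(
                table["X"], table["health"], task="health", classifier=classifier
            )
            path = tmp_path / f"{classifier.replace('+', '_')}.json"
            save_model(model, path)
            loaded = load_model(path)
            assert np.array_equal(
                predict_task(model, table["X"]), predict_task(loaded, table["X"])
            )

    def test_model_files_byte_identical_across_refits(self, small_feature_table, tmp_path):
        table = small_feature_table
        paths = []
        for run in (0, 1):
            model = fit_task_model(table["X"], table["health"], task="health")
            path = tmp_path / f"model_{run}.json"
            save_model(model, path)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()
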