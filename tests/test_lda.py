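"""Fisher discriminant: closed forms, Rayleigh-quotient maximality,
projection/prediction contracts, and serialization."""

import numpy as np
import pytest

import myograsp as mg
from myograsp.errors import DegenerateClassError
from myograsp.lda import fisher_criterion, fit_lda, predict, project

from conftest import gaussian_problem


def small_two_class():
    X = np.array([[1, 2], [2, 3], [3, 3], [6, 5], [7, 8], [8, 5]], dtype=float)
    labels = ["a", "a", "a", "b", "b", "b"]
    return mg.LabeledFeatureSet(X, labels, ["f0", "f1"])


class TestFitLda:
    def test_two_class_closed_form_direction(self):
        m = fit_lda(small_two_class())
        Sw_reg = m.Sw + m.ridge_eps * np.eye(2)
        w_cf = np.linalg.solve(Sw_reg, m.class_means[0] - m.class_means[1])
        cos = abs(w_cf @ m.omega[:, 0]) / np.linalg.norm(w_cf)
        assert cos > 1 - 1e-8

    def test_scatter_matrices_properties(self):
        m = fit_lda(small_two_class())
        np.testing.assert_allclose(m.Sb, m.Sb.T)
        np.testing.assert_allclose(m.Sw, m.Sw.T)
        assert np.all(np.linalg.eigvalsh(m.Sb) > -1e-10)
        assert np.all(np.linalg.eigvalsh(m.Sw) > -1e-10)
        assert np.linalg.matrix_rank(m.Sb, tol=1e-10) <= 1
        # total scatter decomposition St = Sb + Sw
        X = small_two_class().matrix
        St = (X - X.mean(axis=0)).T @ (X - X.mean(axis=0))
        np.testing.assert_allclose(m.Sb + m.Sw, St, rtol=1e-12, atol=1e-9)

    def test_identical_clouds_give_zero_criterion(self):
        X = np.vstack([np.eye(3), np.eye(3)])
        fs = mg.LabeledFeatureSet(X, ["a"] * 3 + ["b"] * 3, ["x", "y", "z"])
        m = fit_lda(fs)
        assert fisher_criterion(m, m.omega[:, 0]) == pytest.approx(0.0, abs=1e-9)

    def test_duplicating_samples_preserves_direction(self):
        fs = small_two_class()
        doubled = mg.LabeledFeatureSet(
            np.vstack([fs.matrix, fs.matrix]),
            np.concatenate([fs.labels, fs.labels]), fs.feature_names)
        m1, m2 = fit_lda(fs, ridge_eps=0.0), fit_lda(doubled, ridge_eps=0.0)
        cos = abs(m1.omega[:, 0] @ m2.omega[:, 0])
        assert cos > 1 - 1e-8

    def test_order_invariance(self):
        fs = small_two_class()
        perm = np.array([3, 0, 5, 2, 4, 1])
        shuffled = mg.LabeledFeatureSet(fs.matrix[perm], fs.labels[perm],
                                        fs.feature_names)
        m1, m2 = fit_lda(fs), fit_lda(shuffled)
        np.testing.assert_array_equal(m1.omega, m2.omega)
        np.testing.assert_array_equal(m1.class_means, m2.class_means)

    def test_generalized_eigen_residual(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            fs = gaussian_problem(rng)
            m = fit_lda(fs)
            Sw_reg = m.Sw + m.ridge_eps * np.eye(m.n_features)
            for j, lam in enumerate(m.eigenvalues):
                w = m.omega[:, j]
                res = np.linalg.norm(m.Sb @ w - lam * (Sw_reg @ w))
                assert res < 1e-8 * np.linalg.norm(m.Sb)

    def test_degenerate_class_rejected(self):
        fs = mg.LabeledFeatureSet(np.eye(3), ["a", "a", "b"], ["x", "y", "z"])
        with pytest.raises(DegenerateClassError):
            fit_lda(fs)

    def test_single_class_rejected(self):
        fs = mg.LabeledFeatureSet(np.eye(3), ["a", "a", "a"], ["x", "y", "z"])
        with pytest.raises(ValueError):
            fit_lda(fs)

    def test_canonical_omega(self):
        m = fit_lda(small_two_class())
        col = m.omega[:, 0]
        assert np.linalg.norm(col) == pytest.approx(1.0)
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        assert col[nz[0]] > 0


class TestFisherCriterion:
    def test_fitted_direction_beats_random(self):
        rng = np.random.default_rng(1)
        fs = gaussian_problem(rng, d=3, n=60)
        m = fit_lda(fs)
        j_star = fisher_criterion(m, m.omega[:, 0])
        for _ in range(1000):
            v = rng.normal(0, 1, 3)
            assert j_star >= fisher_criterion(m, v) - 1e-9

    def test_scale_invariance(self):
        m = fit_lda(small_two_class())
        w = m.omega[:, 0]
        for a in (-3.0, 0.5, 100.0):
            assert fisher_criterion(m, a * w) == pytest.approx(
                fisher_criterion(m, w), rel=1e-12)

    def test_zero_direction_rejected(self):
        m = fit_lda(small_two_class())
        with pytest.raises(ValueError):
            fisher_criterion(m, np.zeros(2))


class TestProjectPredict:
    def test_projected_means_consistency(self):
        m = fit_lda(small_two_class())
        np.testing.assert_array_equal(project(m, m.class_means),
                                      m.projected_means)

    def test_orthogonal_component_invisible(self):
        m = fit_lda(small_two_class())
        w = m.omega[:, 0]
        v = np.array([-w[1], w[0]])  # perpendicular in 2-D
        x = np.array([[1.0, 4.0]])
        np.testing.assert_allclose(project(m, x), project(m, x + 5 * v),
                                   atol=1e-9)

    def test_two_class_projection_is_one_column(self):
        m = fit_lda(small_two_class())
        assert project(m, np.zeros((4, 2))).shape == (4, 1)

    def test_class_mean_predicted_as_own_class(self):
        m = fit_lda(small_two_class())
        y = predict(m, m.class_means)
        assert list(y) == m.class_labels

    def test_midpoint_tie_breaks_to_first_class(self):
        # projected means placed symmetrically around 0: projecting the
        # origin produces an exact distance tie
        m = fit_lda(small_two_class())
        m.projected_means = np.array([[-1.0], [1.0]])
        assert predict(m, np.zeros((1, 2)))[0] == m.class_labels[0]

    def test_separable_clusters_zero_errors(self):
        rng = np.random.default_rng(5)
        fs = gaussian_problem(rng, d=3, n=100, sep=6.0)
        tr, te = mg.split_dataset(fs, mg.SplitSpec(n_train=100, n_test=100, seed=0))
        m = fit_lda(tr)
        assert mg.accuracy(mg.confusion_matrix(te.labels, predict(m, te.matrix))) == 100.0

    def test_dimension_mismatch_rejected(self):
        m = fit_lda(small_two_class())
        with pytest.raises(ValueError):
            predict(m, np.zeros((1, 5)))

    def test_affine_rescaling_consistency(self):
        """Common feature rescaling before refitting leaves predictions fixed."""
        rng = np.random.default_rng(9)
        fs = gaussian_problem(rng, d=4, n=80)
        scale = 12.5
        scaled = mg.LabeledFeatureSet(fs.matrix * scale, fs.labels,
                                      fs.feature_names)
        m1, m2 = fit_lda(fs, ridge_eps=0.0), fit_lda(scaled, ridge_eps=0.0)
        X_new = rng.normal(0.5, 1.5, (50, 4))
        np.testing.assert_array_equal(predict(m1, X_new),
                                      predict(m2, X_new * scale))


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        m = fit_lda(small_two_class())
        path = tmp_path / "model.json"
        m.save(path)
        m2 = mg.LdaModel.load(path)
        np.testing.assert_array_equal(m.omega, m2.omega)
        np.testing.assert_array_equal(m.class_means, m2.class_means)
        assert m.class_labels == m2.class_labels
        assert m.ridge_eps == m2.ridge_eps
        X = np.random.default_rng(0).normal(size=(5, 2))
        np.testing.assert_array_equal(predict(m, X), predict(m2, X))


def test_matches_sklearn_oracle():
    """Cross-check the from-scratch fit against sklearn's LDA on the same data."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    rng = np.random.default_rng(11)
    for _ in range(5):
        fs = gaussian_problem(rng, d=4, n=120, sep=2.5)
        m = fit_lda(fs, ridge_eps=0.0)
        sk = LinearDiscriminantAnalysis(solver="eigen")
        sk.fit(fs.matrix, fs.labels.astype(str))
        w_sk = sk.scalings_[:, 0]
        cos = abs(w_sk @ m.omega[:, 0]) / np.linalg.norm(w_sk)
        assert cos > 1 - 1e-6
        X_new = rng.normal(1.0, 2.0, (80, 4))
        agree = np.mean(predict(m, X_new).astype(str) == sk.predict(X_new))
        assert agree >= 0.97
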