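import numpy as np
import pytest

from specdiscrim.classify import (
    LDAModel,
    PLSDA,
    RBFSVM,
    fit_lda,
    fit_svm_rbf,
    lda_distance,
    lda_distances,
    lda_predict,
    plsda_predict,
    svm_decision,
)


class TestLDAFit:
    def test_hand_computed_1d_case(self):
        # classes {0,2} and {4,6}: sample variance 2 each, pooled 2, means 1 and 5
        X = np.array([[0.0], [2.0], [4.0], [6.0]])
        y = np.array(["a", "a", "b", "b"], object)
        model = fit_lda(X, y)
        np.testing.assert_allclose(model.class_means.ravel(), [1.0, 5.0])
        assert model.pooled_covariance[0, 0] == pytest.approx(2.0)

    def test_singleton_class_rejected(self):
        X = np.array([[0.0], [1.0], [2.0]])
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_lda(X, np.array(["a", "a", "b"], object))

    def test_dimension_must_be_below_sample_count(self, rng):
        X = rng.normal(size=(4, 5))
        with pytest.raises(ValueError, match="dimension"):
            fit_lda(X, np.array(["a", "a", "b", "b"], object))

    def test_pooled_covariance_recovers_shared_structure(self):
        rng = np.random.default_rng(11)
        C = np.array([[2.0, 0.6], [0.6, 1.0]])
        L = np.linalg.cholesky(C)
        Xa = rng.normal(size=(1000, 2)) @ L.T
        Xb = rng.normal(size=(1000, 2)) @ L.T + [5, 5]
        X = np.vstack([Xa, Xb])
        y = np.array(["a"] * 1000 + ["b"] * 1000, object)
        model = fit_lda(X, y)
        np.testing.assert_allclose(model.pooled_covariance, C, rtol=0.15, atol=0.05)


class TestLDADistance:
    def make(self, cov):
        return LDAModel(
            class_list=("a", "b"),
            class_means=np.array([[0.0, 0.0], [4.0, 0.0]]),
            pooled_covariance=np.asarray(cov, float),
        )

    def test_zero_at_class_mean(self):
        m = self.make(np.eye(2))
        assert lda_distance(m, np.zeros(2), 0) == pytest.approx(0.0)

    def test_identity_covariance_is_squared_euclidean(self, rng):
        m = self.make(np.eye(2))
        x = rng.normal(size=2)
        assert lda_distance(m, x, 0) == pytest.approx(float(x @ x))

    def test_diagonal_covariance_hand_case(self):
        m = self.make(np.diag([2.0, 1.0]))
        # x - mean = (1, 1): 1/2 + 1/1 = 1.5
        assert lda_distance(m, np.array([1.0, 1.0]), 0) == pytest.approx(1.5)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            lda_distances(self.make(np.eye(2)), np.ones((1, 3)))


class TestLDAPredict:
    def test_identity_covariance_equals_nearest_centroid(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            means = rng.normal(size=(3, 4))
            model = LDAModel(
                class_list=("a", "b", "c"), class_means=means,
                pooled_covariance=np.eye(4),
            )
            X = rng.normal(size=(10, 4))
            pred = lda_predict(model, X)
            d = ((X[:, None, :] - means[None]) ** 2).sum(axis=2)
            expected = np.array(["abc"[i] for i in d.argmin(axis=1)], object)
            np.testing.assert_array_equal(pred, expected)

    def test_distance_tie_breaks_lexicographically(self):
        model = LDAModel(
            class_list=("a", "b"),
            class_means=np.array([[-1.0], [1.0]]),
            pooled_covariance=np.eye(1),
        )
        assert lda_predict(model, np.array([[0.0]]))[0] == "a"


def svm_dual_oracle(X, y, gamma, C):
    """Independent soft-margin dual solve via scipy SLSQP (not libsvm)."""
    from scipy.optimize import minimize

    n = len(y)
    d2 = ((X[:, None, :] - X[None]) ** 2).sum(axis=2)
    K = np.exp(-gamma * d2)
    Q = (y[:, None] * y[None]) * K

    def neg_dual(a):
        return 0.5 * a @ Q @ a - a.sum()

    res = minimize(
        neg_dual, np.full(n, min(C, 1.0) / 2), jac=lambda a: Q @ a - 1,
        bounds=[(0, C)] * n,
        constraints={"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y},
        method="SLSQP", options={"maxiter": 500, "ftol": 1e-12},
    )
    a = res.x
    sv = a > 1e-8
    margin = (a > 1e-6) & (a < C - 1e-6)
    f_no_b = (a * y) @ K
    b = float(np.mean(y[margin] - f_no_b[margin])) if margin.any() else 0.0
    return f_no_b + b


class TestSVM:
    def test_kernel_of_point_with_itself_is_one(self):
        X = np.array([[0.0], [2.0]])
        y = np.array([-1, 1], object)
        model = fit_svm_rbf(X, y, gamma=5.0, C=100.0)
        # decision at a support vector includes exp(0)=1 for its own term
        d2 = ((model.support_vectors - model.support_vectors[0]) ** 2).sum(axis=1)
        assert np.exp(-model.gamma * d2[0]) == pytest.approx(1.0)

    def test_two_point_analytic_dual(self):
        # x1=0 (y=-1), x2=2 (y=+1), gamma=1, large C:
        # alpha1 = alpha2 = 1/(1 - exp(-4)), bias 0, f(x1)=-1, f(x2)=+1
        X = np.array([[0.0], [2.0]])
        y = np.array([-1, 1], object)
        model = fit_svm_rbf(X, y, gamma=1.0, C=1e6)
        alpha_expected = 1.0 / (1.0 - np.exp(-4.0))
        np.testing.assert_allclose(
            np.abs(model.dual_weights), alpha_expected, rtol=1e-4
        )
        assert model.bias == pytest.approx(0.0, abs=1e-6)
        raw1, sign1 = svm_decision(model, X[0])
        raw2, sign2 = svm_decision(model, X[1])
        assert (sign1, sign2) == (-1, 1)
        assert raw1 == pytest.approx(-1.0, abs=1e-4)
        assert raw2 == pytest.approx(1.0, abs=1e-4)

    def test_dual_constraints_hold(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.array([-1] * 6 + [1] * 6, object)
        model = fit_svm_rbf(X, y, gamma=1.0, C=1.0)
        assert abs(model.dual_weights.sum()) < 1e-6
        assert np.all(np.abs(model.dual_weights) <= 1.0 + 1e-6)

    def test_matches_brute_force_dual_oracle_on_six_points(self):
        X = np.array([[0.0, 0], [0.5, 0.2], [0, 1], [3, 3], [3.5, 2.8], [3, 4]])
        y = np.array([-1, -1, -1, 1, 1, 1], float)
        oracle = svm_dual_oracle(X, y, gamma=1.0, C=10.0)
        model = fit_svm_rbf(X, np.asarray(y, object), gamma=1.0, C=10.0)
        ours = np.array([svm_decision(model, x)[0] for x in X])
        np.testing.assert_allclose(ours, oracle, atol=1e-4)
        assert np.array_equal(np.sign(ours), y)

    def test_huge_gamma_makes_every_point_a_support_vector(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([-1, 1] * 5, object)
        model = fit_svm_rbf(X, y, gamma=1e6, C=1.0)
        assert len(model.support_vectors) == 10

    def test_results_wrapper_predicts_labels(self, rng):
        X = np.vstack([rng.normal(size=(10, 2)), rng.normal(size=(10, 2)) + 4])
        y = np.array(["neg"] * 10 + ["pos"] * 10, object)
        res = RBFSVM(X, y, gamma=1.0, C=1.0).fit()
        assert (res.predict(X) == y).mean() == 1.0


class TestPLSDAPredict:
    def test_separated_training_threshold_midpoint(self):
        rng = np.random.default_rng(31)
        X = np.column_stack([np.repeat([0.0, 1.0], 10), rng.normal(size=20) * 0.01])
        y = np.array(["a"] * 10 + ["b"] * 10, object)
        res = PLSDA(X, y, n_lv=1).fit()
        assert res.classifier.decision_threshold == pytest.approx(0.5, abs=1e-6)
        assert (res.predict(X) == y).all()

    def test_score_at_threshold_goes_to_class_coded_one(self):
        X = np.array([[0.0], [1.0]])
        y = np.array(["a", "b"], object)
        res = PLSDA(X, y, n_lv=1).fit()
        labels, scores = plsda_predict(res.classifier, np.array([[0.5]]))
        assert scores[0] == pytest.approx(res.classifier.decision_threshold)
        assert labels[0] == "b"
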