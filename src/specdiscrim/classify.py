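"""Supervised classifiers: pooled-covariance Mahalanobis LDA, RBF-kernel SVM
and the PLS-DA decision rule.

The LDA here is the non-Bayesian form used in chemometrics: a sample is
assigned to the class whose mean is nearest in squared Mahalanobis distance

    L_ik = (x_i - xbar_k)' C_pooled^{-1} (x_i - xbar_k),

with the covariance pooled over classes (all classes are assumed to share one
variance structure).  Prior probabilities are ignored.  Because spectra have
far more variables than samples, LDA consumes reduced scores (PCA scores or a
GA-selected variable subset), never the raw spectrum when d >= n.

Model classes follow the statsmodels convention: construct with data, call
``fit()`` for a results object carrying the estimates, ``predict`` and
``summary``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.svm import SVC

from .decomposition import (
    PLSModel,
    choose_n_lv,
    fit_pca,
    fit_pls,
    n_components_for_variance,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LDAModel",
    "fit_lda",
    "lda_distance",
    "lda_distances",
    "lda_predict",
    "SVMModel",
    "fit_svm_rbf",
    "svm_decision",
    "PLSDAClassifier",
    "plsda_predict",
    "PLSDA",
    "PCALDA",
    "RBFSVM",
]


# ---------------------------------------------------------------------------
# Pooled-covariance LDA


@dataclass(frozen=True)
class LDAModel:
    class_list: tuple
    class_means: np.ndarray       # (K, d)
    pooled_covariance: np.ndarray  # (d, d), symmetric positive-definite
    _cho: tuple = None  # type: ignore[assignment]

    def __post_init__(self):
        C = np.asarray(self.pooled_covariance, float)
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("pooled covariance must be symmetric")
        object.__setattr__(self, "_cho", cho_factor(C))

    def solve(self, B: np.ndarray) -> np.ndarray:
        return cho_solve(self._cho, B)


def fit_lda(scores: np.ndarray, labels) -> LDAModel:
    """Fit class means and the pooled within-class covariance.

    C_pooled = sum_k (n_k - 1) S_k / (n - K).  A near-singular pooled matrix
    is ridge-regularized with lambda = 1e-8 * trace/d (logged).
    """
    X = np.asarray(scores, float)
    y = np.asarray(labels, object)
    n, d = X.shape
    classes = tuple(sorted(set(y.tolist()), key=str))
    K = len(classes)
    if K < 2:
        raise ValueError("need at least 2 classes")
    if d >= n:
        raise ValueError(
            f"score dimension ({d}) must be < number of samples ({n}); "
            "reduce with PCA or variable selection first"
        )
    means = np.empty((K, d))
    Sw = np.zeros((d, d))
    for i, c in enumerate(classes):
        Xi = X[y == c]
        if Xi.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        means[i] = Xi.mean(axis=0)
        Sw += (Xi.shape[0] - 1) * np.cov(Xi, rowvar=False, ddof=1)
    C = Sw / (n - K)
    C = 0.5 * (C + C.T)
    try:
        cho_factor(C)
        singular = False
    except np.linalg.LinAlgError:
        singular = True
    if singular or np.linalg.cond(C) > 1e12:
        lam = 1e-8 * np.trace(C) / d
        if lam <= 0:
            lam = 1e-12
        logger.warning("pooled covariance near-singular; ridge lambda=%.3e applied", lam)
        C = C + lam * np.eye(d)
    return LDAModel(class_list=classes, class_means=means, pooled_covariance=C)


def lda_distances(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distance of each row to each class mean; (n, K)."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.class_means.shape[1]:
        raise ValueError("dimension mismatch with class means")
    out = np.empty((X.shape[0], len(model.class_list)))
    for k in range(len(model.class_list)):
        D = X - model.class_means[k]
        out[:, k] = np.einsum("ij,ij->i", D, model.solve(D.T).T)
    return np.maximum(out, 0.0)


def lda_distance(model: LDAModel, x: np.ndarray, k: int) -> float:
    """Squared Mahalanobis distance of one sample to class k's mean."""
    return float(lda_distances(model, np.atleast_2d(x))[0, k])


def lda_predict(model: LDAModel, X: np.ndarray):
    """Assign each row to the class with minimum distance; distance ties break
    toward the lexicographically first class label."""
    L = lda_distances(model, X)
    idx = np.argmin(L, axis=1)  # argmin returns the first minimum: class_list is sorted
    return np.array([model.class_list[i] for i in idx], dtype=object)


# ---------------------------------------------------------------------------
# RBF-kernel SVM (soft-margin dual via libsvm)


@dataclass(frozen=True)
class SVMModel:
    support_vectors: np.ndarray
    dual_weights: np.ndarray  # alpha_i * y_i per support vector
    bias: float
    gamma: float
    box_constraint: float
    classes: tuple  # (negative_label, positive_label) mapped to (-1, +1)


def fit_svm_rbf(X: np.ndarray, y, gamma: float = 1.0, C: float = 1.0) -> SVMModel:
    """Solve the soft-margin RBF-SVM dual, k(x, z) = exp(-gamma ||x - z||^2).

    ``y`` may be any two labels; they are coded -1/+1 in sorted order.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, object)
    classes = tuple(sorted(set(y.tolist()), key=str))
    if len(classes) != 2:
        raise ValueError("binary SVM requires exactly two classes")
    ypm = np.where(y == classes[1], 1, -1)
    svc = SVC(kernel="rbf", gamma=gamma, C=C, tol=1e-7)
    svc.fit(X, ypm)
    if getattr(svc, "fit_status_", 0) != 0:
        raise RuntimeError("SVM optimizer did not converge")
    return SVMModel(
        support_vectors=svc.support_vectors_.copy(),
        dual_weights=svc.dual_coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        gamma=gamma,
        box_constraint=C,
        classes=classes,
    )


def svm_decision(model: SVMModel, x: np.ndarray) -> tuple[float, int]:
    """Decision value f(x) = sum_j alpha_j y_j k(x, z_j) + b and its sign."""
    x = np.asarray(x, float)
    d2 = np.sum((model.support_vectors - x) ** 2, axis=1)
    raw = float(model.dual_weights @ np.exp(-model.gamma * d2) + model.bias)
    return raw, (1 if raw >= 0 else -1)


def _svm_decision_batch(model: SVMModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, float))
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(model.support_vectors**2, axis=1)[None, :]
        - 2.0 * X @ model.support_vectors.T
    )
    return np.exp(-model.gamma * np.maximum(d2, 0)) @ model.dual_weights + model.bias


# ---------------------------------------------------------------------------
# PLS-DA decision rule


@dataclass(frozen=True)
class PLSDAClassifier:
    pls: PLSModel
    decision_threshold: float
    classes: tuple  # (class coded 0, class coded 1)

    def __post_init__(self):
        if not np.isfinite(self.decision_threshold):
            raise ValueError("decision threshold must be finite")


def plsda_predict(clf: PLSDAClassifier, X: np.ndarray):
    """Labels and continuous predicted responses.

    The threshold is the midpoint of the two training-class mean responses; a
    score exactly at the threshold goes to the class coded 1.
    """
    scores = clf.pls.predict(np.atleast_2d(np.asarray(X, float)))
    labels = np.where(scores >= clf.decision_threshold, clf.classes[1], clf.classes[0])
    return labels.astype(object), scores


# ---------------------------------------------------------------------------
# Model/Results wrappers


class _ResultsBase:
    """Common results API: predict, decision_scores, summary."""

    def predict(self, X):  # pragma: no cover - abstract
        raise NotImplementedError

    def decision_scores(self, X):  # pragma: no cover - abstract
        raise NotImplementedError

    def summary(self) -> str:
        lines = [f"{type(self).__name__}"]
        for k, v in self._summary_fields():
            lines.append(f"  {k}: {v}")
        return "\n".join(lines)

    def _summary_fields(self):
        return []


class PLSDA:
    """PLS discriminant analysis on preprocessed spectra.

    Parameters
    ----------
    X : (n, m) preprocessed intensity matrix.
    y : n class labels (two classes).  The lexicographically second class is
        coded 1 and is the positive direction of the decision score.
    n_lv : latent-variable count, or None to select by leave-one-out CV.
    max_lv : search bound when ``n_lv`` is None.
    """

    def __init__(self, X, y, n_lv: int | None = None, max_lv: int = 10):
        self.X = np.asarray(X, float)
        self.y = np.asarray(y, object)
        self.classes = tuple(sorted(set(self.y.tolist()), key=str))
        if len(self.classes) != 2:
            raise ValueError("PLS-DA here is binary; got classes " + repr(self.classes))
        self.n_lv = n_lv
        self.max_lv = max_lv

    def fit(self) -> "PLSDAResults":
        y_code = np.where(self.y == self.classes[1], 1.0, 0.0)
        n_lv = self.n_lv
        if n_lv is None:
            cap = min(self.max_lv, self.X.shape[0] - 2, self.X.shape[1])
            n_lv = choose_n_lv(self.X, y_code, cap)
        model = fit_pls(self.X, y_code, n_lv)
        pred = model.predict(self.X)
        thr = 0.5 * (pred[y_code == 0].mean() + pred[y_code == 1].mean())
        clf = PLSDAClassifier(pls=model, decision_threshold=thr, classes=self.classes)
        return PLSDAResults(self, clf)


class PLSDAResults(_ResultsBase):
    def __init__(self, model: PLSDA, clf: PLSDAClassifier):
        self.model = model
        self.classifier = clf

    @property
    def coefficients(self) -> np.ndarray:
        return self.classifier.pls.coefficients

    @property
    def n_lv(self) -> int:
        return self.classifier.pls.n_lv

    def predict(self, X):
        return plsda_predict(self.classifier, X)[0]

    def decision_scores(self, X):
        return plsda_predict(self.classifier, X)[1]

    def _summary_fields(self):
        return [
            ("classes", self.model.classes),
            ("latent variables", self.n_lv),
            ("decision threshold", f"{self.classifier.decision_threshold:.4f}"),
        ]


class PCALDA:
    """PCA score reduction followed by pooled-covariance Mahalanobis LDA.

    ``n_pc=None`` takes the smallest k reaching 95% cumulative explained
    variance, capped at n - K - 1 so the pooled covariance stays estimable.
    """

    def __init__(self, X, y, n_pc: int | None = None, variance_threshold: float = 0.95):
        self.X = np.asarray(X, float)
        self.y = np.asarray(y, object)
        self.classes = tuple(sorted(set(self.y.tolist()), key=str))
        self.n_pc = n_pc
        self.variance_threshold = variance_threshold

    def fit(self) -> "PCALDAResults":
        n, K = self.X.shape[0], len(self.classes)
        cap = max(1, n - K - 1)
        k = self.n_pc if self.n_pc is not None else n_components_for_variance(
            self.X, self.variance_threshold, cap=cap
        )
        pca = fit_pca(self.X, k)
        lda = fit_lda(pca.scores, self.y)
        return PCALDAResults(self, pca, lda)


class PCALDAResults(_ResultsBase):
    def __init__(self, model: PCALDA, pca, lda: LDAModel):
        self.model = model
        self.pca = pca
        self.lda = lda

    def predict(self, X):
        return lda_predict(self.lda, self.pca.transform(X))

    def decision_scores(self, X):
        # larger = closer to the last (lexicographically second) class
        L = lda_distances(self.lda, self.pca.transform(X))
        return L[:, 0] - L[:, -1]

    def _summary_fields(self):
        return [
            ("classes", self.lda.class_list),
            ("principal components", self.pca.scores.shape[1]),
        ]


class RBFSVM:
    """Soft-margin SVM with the radial basis kernel (default gamma=1, C=1).

    ``tune_C=True`` picks C from {0.1, 1, 10} by an internal Venetian-blinds
    validation split of the training data.
    """

    def __init__(self, X, y, gamma: float = 1.0, C: float = 1.0, tune_C: bool = False):
        self.X = np.asarray(X, float)
        self.y = np.asarray(y, object)
        self.gamma = gamma
        self.C = C
        self.tune_C = tune_C

    def fit(self) -> "RBFSVMResults":
        C = self.C
        if self.tune_C:
            C = self._select_C((0.1, 1.0, 10.0))
        model = fit_svm_rbf(self.X, self.y, gamma=self.gamma, C=C)
        return RBFSVMResults(self, model)

    def _select_C(self, grid) -> float:
        from .metrics import venetian_folds

        folds = venetian_folds(self.X.shape[0], min(3, self.X.shape[0])).fold
        best, best_err = grid[0], np.inf
        for C in grid:
            err = 0
            for f in np.unique(folds):
                tr = folds != f
                if len(set(self.y[tr].tolist())) < 2:
                    continue
                m = fit_svm_rbf(self.X[tr], self.y[tr], gamma=self.gamma, C=C)
                raw = _svm_decision_batch(m, self.X[~tr])
                pred = np.where(raw >= 0, m.classes[1], m.classes[0])
                err += int(np.sum(pred != self.y[~tr]))
            if err < best_err:
                best, best_err = C, err
        logger.info("SVM internal validation selected C=%s", best)
        return best


class RBFSVMResults(_ResultsBase):
    def __init__(self, model: RBFSVM, svm: SVMModel):
        self.model = model
        self.svm = svm

    def predict(self, X):
        raw = _svm_decision_batch(self.svm, X)
        return np.where(raw >= 0, self.svm.classes[1], self.svm.classes[0]).astype(object)

    def decision_scores(self, X):
        return _svm_decision_batch(self.svm, X)

    def _summary_fields(self):
        return [
            ("classes", self.svm.classes),
            ("support vectors", len(self.svm.dual_weights)),
            ("gamma", self.svm.gamma),
            ("C", self.svm.box_constraint),
        ]
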