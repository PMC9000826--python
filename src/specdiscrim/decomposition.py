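"""Latent-variable decompositions: PCA and single-response NIPALS PLS.

PCA provides exploratory reduction and the score space consumed by
pooled-covariance LDA.  PLS extracts latent variables maximizing the
covariance between the (centered) spectra and a centered binary class code;
the regression coefficient vector over wavenumbers is the biomarker readout:
its large-magnitude local maxima point at the discriminating bands.

Both use fixed deterministic sign conventions (the largest-magnitude loading
or weight element is made positive) so repeated fits are bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PCAModel",
    "PLSModel",
    "fit_pca",
    "fit_pls",
    "choose_n_lv",
    "pls_coefficients",
    "top_peaks",
]


@dataclass(frozen=True)
class PCAModel:
    loadings: np.ndarray                     # (m, k), orthonormal columns
    scores: np.ndarray                       # (n, k)
    explained_variance_fraction: np.ndarray  # (k,)
    training_column_means: np.ndarray        # (m,)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.training_column_means) @ self.loadings


def _flip_to_positive_max(v: np.ndarray) -> float:
    """Return +-1 so that the largest-|.| element of v becomes positive."""
    i = int(np.argmax(np.abs(v)))
    return 1.0 if v[i] >= 0 else -1.0


def fit_pca(X: np.ndarray, k: int) -> PCAModel:
    """PCA by SVD of the column-centered matrix.

    Components are ordered by decreasing explained variance;
    ``explained_variance_fraction`` is relative to the total variance of the
    centered data (so it sums to 1 over all ``min(n-1, m)`` components).
    """
    X = np.asarray(X, float)
    n, m = X.shape
    kmax = min(n - 1, m)
    if not 1 <= k <= kmax:
        raise ValueError(f"k={k} out of range [1, {kmax}]")
    mu = X.mean(axis=0)
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s**2).sum())
    loadings = np.empty((m, k))
    scores = np.empty((n, k))
    for j in range(k):
        sign = _flip_to_positive_max(Vt[j])
        loadings[:, j] = sign * Vt[j]
        scores[:, j] = sign * U[:, j] * s[j]
    frac = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PCAModel(loadings, scores, frac, mu)


def n_components_for_variance(
    X: np.ndarray, threshold: float = 0.95, cap: int | None = None
) -> int:
    """Smallest k whose cumulative explained-variance fraction >= threshold,
    optionally capped (used to bound the LDA score dimension below n)."""
    X = np.asarray(X, float)
    kmax = min(X.shape[0] - 1, X.shape[1])
    full = fit_pca(X, kmax)
    cum = np.cumsum(full.explained_variance_fraction)
    k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    k = min(k, kmax)
    if cap is not None:
        k = max(1, min(k, cap))
    return k


@dataclass(frozen=True)
class PLSModel:
    """Single-response PLS (PLS1) fitted by NIPALS deflation."""

    n_lv: int
    x_weights: np.ndarray    # (m, n_lv)
    x_loadings: np.ndarray   # (m, n_lv)
    y_loadings: np.ndarray   # (n_lv,)
    x_scores: np.ndarray     # (n, n_lv)
    coefficients: np.ndarray  # (m,)
    x_means: np.ndarray
    y_mean: float

    @property
    def intercept(self) -> float:
        return self.y_mean - float(self.x_means @ self.coefficients)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.coefficients + self.intercept


def fit_pls(X: np.ndarray, y_code: np.ndarray, n_lv: int) -> PLSModel:
    """Fit PLS1 with ``n_lv`` latent variables by sequential NIPALS extraction.

    ``y_code`` is the class-indicator response (e.g. 0/1); it is centered
    internally.  For a single response the NIPALS weight step is closed-form:
    w_a proportional to X_a' y_a.
    """
    X = np.asarray(X, float)
    y = np.asarray(y_code, float)
    n, m = X.shape
    if y.shape != (n,):
        raise ValueError("y_code must be a length-n vector")
    if np.ptp(y) == 0:
        raise ValueError("degenerate (zero-variance) response")
    if not 1 <= n_lv <= min(n - 1, m):
        raise ValueError(f"n_lv={n_lv} out of range [1, {min(n - 1, m)}]")
    x_means = X.mean(axis=0)
    y_mean = float(y.mean())
    Xa = X - x_means
    ya = y - y_mean
    W = np.empty((m, n_lv))
    P = np.empty((m, n_lv))
    q = np.empty(n_lv)
    T = np.empty((n, n_lv))
    for a in range(n_lv):
        w = Xa.T @ ya
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError(f"response fully deflated after {a} latent variables")
        w /= nw
        sign = _flip_to_positive_max(w)
        w *= sign
        t = Xa @ w
        tt = float(t @ t)
        if tt == 0:
            raise ValueError(f"zero-variance score at latent variable {a + 1}")
        p = Xa.T @ t / tt
        qa = float(ya @ t) / tt
        Xa = Xa - np.outer(t, p)
        ya = ya - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p, qa, t
    # B = W (P'W)^-1 q maps centered X to centered predicted response
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(n_lv, W, P, q, T, coef, x_means, y_mean)


def _coefficients_per_lv(X: np.ndarray, y: np.ndarray, max_lv: int) -> np.ndarray:
    """Coefficient vectors for 1..max_lv LVs from one NIPALS pass; (max_lv, m)."""
    model = fit_pls(X, y, max_lv)
    W, P, q = model.x_weights, model.x_loadings, model.y_loadings
    out = np.empty((max_lv, X.shape[1]))
    for a in range(1, max_lv + 1):
        out[a - 1] = W[:, :a] @ np.linalg.solve(P[:, :a].T @ W[:, :a], q[:a])
    return out


def choose_n_lv(X: np.ndarray, y_code: np.ndarray, max_lv: int) -> int:
    """Number of latent variables minimizing leave-one-out misclassification.

    For each left-out sample the model is refitted on the rest; a sample is
    classed 1 when its predicted response exceeds the midpoint of the two
    training-class mean predictions.  Ties between LV counts break toward the
    smallest count.
    """
    X = np.asarray(X, float)
    y = np.asarray(y_code, float)
    n = X.shape[0]
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    if max_lv >= n:
        raise ValueError(f"max_lv ({max_lv}) must be < n ({n}) for leave-one-out")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("binary response required")
    errors = np.zeros(max_lv, dtype=int)
    for i in range(n):
        keep = np.ones(n, bool)
        keep[i] = False
        Xtr, ytr = X[keep], y[keep]
        if np.ptp(ytr) == 0:
            raise ValueError("leave-one-out leaves a single-class training set")
        cap = min(max_lv, Xtr.shape[0] - 1, Xtr.shape[1])
        coefs = _coefficients_per_lv(Xtr, ytr, cap)
        mu_x = Xtr.mean(axis=0)
        mu_y = ytr.mean()
        for a in range(max_lv):
            b = coefs[min(a, cap - 1)]
            pred_tr = (Xtr - mu_x) @ b + mu_y
            thr = 0.5 * (pred_tr[ytr == classes[0]].mean() + pred_tr[ytr == classes[1]].mean())
            pred_i = float((X[i] - mu_x) @ b + mu_y)
            label = classes[1] if pred_i >= thr else classes[0]
            if label != y[i]:
                errors[a] += 1
    return int(np.argmin(errors)) + 1  # argmin takes the first (smallest) on ties


def pls_coefficients(model: PLSModel) -> np.ndarray:
    """The length-m regression vector mapping centered spectra to the response."""
    return model.coefficients.copy()


def top_peaks(
    coefficients: np.ndarray,
    axis: np.ndarray,
    k: int,
    min_separation_cm1: float = 10.0,
) -> list[float]:
    """Wavenumbers of the k largest local maxima of |coefficient|.

    Peaks are ranked by |coefficient| and greedily accepted subject to a
    minimum mutual separation on the wavenumber axis.  If fewer than k
    qualifying maxima exist, all of them are returned (logged).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    c = np.abs(np.asarray(coefficients, float))
    axis = np.asarray(axis, float)
    if c.shape != axis.shape:
        raise ValueError("coefficient vector and axis length differ")
    interior = (c[1:-1] >= c[:-2]) & (c[1:-1] >= c[2:])
    cand = np.where(interior)[0] + 1
    # axis endpoints count as local maxima when they dominate their neighbour
    if c.size >= 2 and c[0] > c[1]:
        cand = np.concatenate([[0], cand])
    if c.size >= 2 and c[-1] > c[-2]:
        cand = np.concatenate([cand, [c.size - 1]])
    cand = cand[c[cand] > 0]  # zero plateaus are not peaks
    cand = cand[np.argsort(c[cand])[::-1]]
    chosen: list[float] = []
    for idx in cand:
        wn = axis[idx]
        if all(abs(wn - prev) >= min_separation_cm1 for prev in chosen):
            chosen.append(float(wn))
        if len(chosen) == k:
            break
    if len(chosen) < k:
        logger.warning("top_peaks: only %d/%d separated local maxima found", len(chosen), k)
    return chosen
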