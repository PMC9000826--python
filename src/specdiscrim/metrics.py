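"""Cross-validation schemes, diagnostic metrics and the Training/CV/Test
evaluation protocol.

The metric suite reports accuracy, sensitivity and specificity as percentages
plus two composite scores used for imbalanced diagnostic data: the F-score
(here the harmonic mean of sensitivity and specificity, not the
precision/recall F1) and the G-score (geometric mean of sensitivity and
specificity).  Integer reporting rounds half away from zero.

Cross-validation is "Venetian blinds": row i of the dataset goes to fold
``i % k``.  In the evaluation protocol folds are assigned at the *sample*
level so that replicate spectra of one sample never straddle folds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

logger = logging.getLogger(__name__)

__all__ = [
    "FoldAssignment",
    "ConfusionCounts",
    "MetricsReport",
    "venetian_folds",
    "loo_folds",
    "confusion",
    "metrics_from_counts",
    "metrics_from_rates",
    "round_half_away",
    "roc_auc",
    "evaluate_protocol",
    "ProtocolResults",
]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class FoldAssignment:
    fold: np.ndarray  # fold index per row
    k: int

    def __post_init__(self):
        f = np.asarray(self.fold, int)
        counts = np.bincount(f, minlength=self.k)
        if (counts == 0).any():
            raise ValueError("every fold must be non-empty")
        object.__setattr__(self, "fold", f)


def venetian_folds(n: int, k: int) -> FoldAssignment:
    """Venetian-blinds assignment: row i (dataset order) -> fold i mod k."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    return FoldAssignment(fold=np.arange(n) % k, k=k)


def loo_folds(n: int) -> FoldAssignment:
    """Leave-one-out: n singleton folds."""
    if n < 2:
        raise ValueError("leave-one-out needs n >= 2")
    return FoldAssignment(fold=np.arange(n), k=n)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(true_labels, predicted_labels, positive_label) -> ConfusionCounts:
    t = np.asarray(true_labels, object)
    p = np.asarray(predicted_labels, object)
    if t.shape != p.shape:
        raise ValueError("label vectors differ in length")
    tp = int(np.sum((t == positive_label) & (p == positive_label)))
    fn = int(np.sum((t == positive_label) & (p != positive_label)))
    fp = int(np.sum((t != positive_label) & (p == positive_label)))
    tn = int(np.sum((t != positive_label) & (p != positive_label)))
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


@dataclass(frozen=True)
class MetricsReport:
    """Percent-scale diagnostic metrics for one evaluation block.

    ``sensitivity``/``specificity`` are None (flagged missing, never silently
    0) when no positive/negative samples were evaluated.
    """

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    f_score: float | None
    g_score: float | None
    auc: float | None
    n: int

    def rounded(self) -> dict:
        def r(v):
            return None if v is None else round_half_away(v)

        return {
            "accuracy": r(self.accuracy),
            "sensitivity": r(self.sensitivity),
            "specificity": r(self.specificity),
            "f_score": r(self.f_score),
            "g_score": r(self.g_score),
            "auc": None if self.auc is None else round(self.auc, 2),
            "n": self.n,
        }


def metrics_from_rates(
    sens_pct: float, spec_pct: float, literal_g: bool = False
) -> tuple[float, float]:
    """F-score and G-score from percent-scale sensitivity and specificity.

    F = harmonic mean, G = geometric mean.  ``literal_g=True`` computes the
    plain product/100 form instead (kept for comparison; it does not reproduce
    the geometric-mean scores this suite reports).
    """
    if sens_pct + spec_pct == 0:
        fs = 0.0
    else:
        fs = 2.0 * sens_pct * spec_pct / (sens_pct + spec_pct)
    gs = (sens_pct * spec_pct) / 100.0 if literal_g else math.sqrt(sens_pct * spec_pct)
    return fs, gs


def metrics_from_counts(
    counts: ConfusionCounts, auc: float | None = None, literal_g: bool = False
) -> MetricsReport:
    if counts.n == 0:
        raise ValueError("empty confusion counts")
    acc = 100.0 * (counts.TP + counts.TN) / counts.n
    sens = None
    if counts.TP + counts.FN > 0:
        sens = 100.0 * counts.TP / (counts.TP + counts.FN)
    else:
        logger.warning("no positive samples evaluated; sensitivity flagged missing")
    spec = None
    if counts.TN + counts.FP > 0:
        spec = 100.0 * counts.TN / (counts.TN + counts.FP)
    else:
        logger.warning("no negative samples evaluated; specificity flagged missing")
    fs = gs = None
    if sens is not None and spec is not None:
        fs, gs = metrics_from_rates(sens, spec, literal_g=literal_g)
    return MetricsReport(acc, sens, spec, fs, gs, auc, counts.n)


def roc_auc(scores, binary_labels, positive_label) -> tuple[np.ndarray, float]:
    """ROC curve points (FPR, TPR) and trapezoidal AUC.

    Equivalent to the Mann-Whitney pair-counting statistic: tied scores
    contribute one half.
    """
    y = np.asarray([1 if l == positive_label else 0 for l in binary_labels])
    s = np.asarray(scores, float)
    if y.min() == y.max():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    return np.column_stack([fpr, tpr]), auc


# ---------------------------------------------------------------------------
# Training / CV / Test protocol


@dataclass(frozen=True)
class ProtocolResults:
    """Metric reports for the three evaluation blocks of one model run."""

    training: MetricsReport
    cv: MetricsReport
    test: MetricsReport
    scheme: str | None = None
    model_name: str | None = None

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, rep in (
            ("Training: TPS", self.training),
            ("CV: TPS", self.cv),
            ("Test: MPS", self.test),
        ):
            d = rep.rounded()
            rows.append(
                {
                    "spectral_data": name,
                    "accuracy": d["accuracy"],
                    "sensitivity": d["sensitivity"],
                    "specificity": d["specificity"],
                    "f_score": d["f_score"],
                    "g_score": d["g_score"],
                    "auc": d["auc"],
                    "n": d["n"],
                }
            )
        df = pd.DataFrame(rows)
        if self.scheme is not None:
            df.insert(0, "scheme", self.scheme)
        if self.model_name is not None:
            df.insert(1 if self.scheme is not None else 0, "model", self.model_name)
        return df


def _sample_level_folds(sample_ids: np.ndarray, k: int) -> np.ndarray:
    """Venetian blinds over distinct samples (first-appearance order); each
    spectrum inherits its sample's fold, so replicates never straddle folds."""
    order: dict = {}
    for s in sample_ids:
        if s not in order:
            order[s] = len(order)
    n_samples = len(order)
    if k > n_samples:
        raise ValueError(f"k={k} exceeds number of samples ({n_samples})")
    return np.array([order[s] % k for s in sample_ids], int)


def evaluate_protocol(
    model_factory,
    X_total: np.ndarray,
    labels_total,
    sample_ids,
    X_mean: np.ndarray,
    labels_mean,
    positive_label,
    cv: str = "venetian",
    k: int = 10,
    fold_granularity: str = "sample",
    holdout_samples=None,
) -> ProtocolResults:
    """Evaluate one classifier under the three-block protocol.

    Training block: fit on all replicate spectra (TPS), resubstitution
    predictions.  CV block: refit per fold (Venetian blinds or leave-one-out,
    folds at the sample level by default).  Test block: the model fitted on
    all TPS predicts the per-sample mean spectra (MPS).  Note the mean spectra
    derive from the training samples, so the default Test block is a
    consistency check, not an independent validation; pass ``holdout_samples``
    (sample ids) for an honest mode that removes those samples from the
    Training/CV blocks entirely and uses their rows of ``X_mean`` as the test
    set.

    ``model_factory(X, y)`` must return a fitted results object exposing
    ``predict(X) -> labels`` and ``decision_scores(X) -> float array`` whose
    larger values favour the positive class.
    """
    X_total = np.asarray(X_total, float)
    y_total = np.asarray(labels_total, object)
    y_mean = np.asarray(labels_mean, object)
    X_mean = np.asarray(X_mean, float)
    sample_ids = np.asarray(sample_ids, object)
    if holdout_samples is not None:
        held = set(holdout_samples)
        mean_ids = np.array(list(dict.fromkeys(sample_ids.tolist())), object)
        if X_mean.shape[0] != mean_ids.size:
            raise ValueError("holdout mode expects one mean spectrum per sample, in sample order")
        keep_mean = np.array([s in held for s in mean_ids])
        if not keep_mean.any():
            raise ValueError("no held-out samples found among the mean spectra")
        keep_total = np.array([s not in held for s in sample_ids])
        X_mean, y_mean = X_mean[keep_mean], y_mean[keep_mean]
        X_total, y_total = X_total[keep_total], y_total[keep_total]
        sample_ids = sample_ids[keep_total]
    n = X_total.shape[0]

    def block(res, X, y) -> MetricsReport:
        pred = res.predict(X)
        scores = res.decision_scores(X)
        counts = confusion(y, pred, positive_label)
        auc = None
        if len(set(y.tolist())) == 2:
            _, auc = roc_auc(scores, y, positive_label)
        return metrics_from_counts(counts, auc=auc)

    full = model_factory(X_total, y_total)
    training = block(full, X_total, y_total)
    test = block(full, X_mean, y_mean)

    if fold_granularity == "sample":
        folds = _sample_level_folds(sample_ids, k if cv == "venetian" else
                                    len(dict.fromkeys(sample_ids.tolist())))
    elif fold_granularity == "spectrum":
        fa = venetian_folds(n, k) if cv == "venetian" else loo_folds(n)
        folds = fa.fold
    else:
        raise ValueError("fold_granularity must be 'sample' or 'spectrum'")
    pred_cv = np.empty(n, object)
    score_cv = np.empty(n, float)
    for f in np.unique(folds):
        tr = folds != f
        te = ~tr
        if len(set(y_total[tr].tolist())) < 2:
            raise ValueError(f"fold {f}: training split lost a class; reduce k")
        res = model_factory(X_total[tr], y_total[tr])
        pred_cv[te] = res.predict(X_total[te])
        score_cv[te] = res.decision_scores(X_total[te])
    counts = confusion(y_total, pred_cv, positive_label)
    auc = None
    if len(set(y_total.tolist())) == 2:
        _, auc = roc_auc(score_cv, y_total, positive_label)
    cv_report = metrics_from_counts(counts, auc=auc)
    return ProtocolResults(training=training, cv=cv_report, test=test)
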