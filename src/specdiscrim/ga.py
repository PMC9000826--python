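"""Genetic-algorithm wavenumber selection scored by a Mahalanobis-ratio cost,
composed with pooled-covariance LDA (GA-LDA).

Each chromosome is a binary mask over the m wavenumber variables.  Its cost is

    G = (1/NV) * sum_n g_n,
    g_n = r^2(x_n, mean of own class) / min over wrong classes of
          r^2(x_n, mean of wrong class),

where r^2 is the squared Mahalanobis distance under the pooled covariance of
the *training* rows restricted to the selected variables, and the sum runs
over NV held-back validation rows.  g_n < 1 means the sample sits closer to
its own class; fitness is 1/G (capped when G underflows on perfectly
separated data).

The evolutionary operators (tournament selection of size 2, single-point
crossover, bitwise mutation, repair to the feature-count bounds, elitism) are
standard choices; the mutation probability is interpreted as a per-chromosome
expected flip budget — the per-bit rate is p_mutation * popcount / m, giving
p_mutation * popcount expected flips.  A literal 10% per-bit rate over ~1000
wavenumbers would randomize every chromosome each generation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classify import LDAModel, fit_lda, lda_predict

logger = logging.getLogger(__name__)

__all__ = ["GAConfig", "GARun", "gn_ratio", "cost_G", "run_ga", "ga_lda_classify"]

_FITNESS_CAP = 1.0 / 1e-12


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 200
    generations: int = 100
    p_mutation: float = 0.10
    p_crossover: float = 0.60
    seed: int = 0
    min_features: int = 2
    max_features: int = 30
    elitism_count: int = 1
    #: folds of the internal Venetian-blinds split providing validation rows
    cost_folds: int = 3

    def __post_init__(self):
        if not (0 <= self.p_mutation <= 1 and 0 <= self.p_crossover <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if not 1 <= self.min_features <= self.max_features:
            raise ValueError("need 1 <= min_features <= max_features")
        if self.population_size < 2 or self.generations < 1:
            raise ValueError("population_size >= 2 and generations >= 1 required")
        if self.elitism_count < 0 or self.elitism_count >= self.population_size:
            raise ValueError("elitism_count must be in [0, population_size)")


@dataclass(frozen=True)
class GARun:
    best_chromosome: np.ndarray
    best_fitness_history: np.ndarray  # one value per generation
    seed: int

    @property
    def selected_indices(self) -> np.ndarray:
        return np.where(self.best_chromosome)[0]


def _class_stats(X: np.ndarray, y: np.ndarray):
    """Class means and pooled covariance (ridge-stabilized when needed)."""
    classes = sorted(set(y.tolist()), key=str)
    K = len(classes)
    if K < 2:
        raise ValueError("need >= 2 classes")
    n, d = X.shape
    means = {}
    Sw = np.zeros((d, d))
    for c in classes:
        Xi = X[y == c]
        means[c] = Xi.mean(axis=0)
        if Xi.shape[0] > 1:
            Sw += (Xi.shape[0] - 1) * np.cov(Xi, rowvar=False, ddof=1).reshape(d, d)
    C = Sw / max(n - K, 1)
    C = 0.5 * (C + C.T)
    try:
        Cinv = np.linalg.inv(C)
        if not np.all(np.isfinite(Cinv)) or np.linalg.cond(C) > 1e10:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        lam = 1e-8 * np.trace(C) / d
        if lam <= 0:
            lam = 1e-12
        Cinv = np.linalg.inv(C + lam * np.eye(d))
    return classes, means, Cinv


def gn_ratio(x: np.ndarray, class_means: dict, cov_inverse: np.ndarray, own_class) -> float:
    """Ratio of squared Mahalanobis distances: own class over nearest wrong class.

    0 at the own-class mean; 1 when equidistant; +inf (sentinel, logged) when
    x sits exactly at a wrong-class mean.
    """
    x = np.asarray(x, float)
    d_own = None
    d_wrong = np.inf
    for c, mu in class_means.items():
        diff = x - mu
        r2 = float(diff @ cov_inverse @ diff)
        if c == own_class:
            d_own = r2
        else:
            d_wrong = min(d_wrong, r2)
    if d_own is None:
        raise ValueError(f"own class {own_class!r} not among the class means")
    if d_wrong == 0.0:
        logger.warning("validation sample coincides with a wrong-class mean; gn = inf")
        return np.inf
    return max(d_own, 0.0) / d_wrong


def cost_G(
    chromosome: np.ndarray,
    X: np.ndarray,
    labels,
    validation_index_set,
) -> float:
    """Mean gn over the validation rows; class statistics come from the
    remaining (training) rows restricted to the chromosome's variables."""
    mask = np.asarray(chromosome, bool)
    if mask.sum() == 0:
        raise ValueError("chromosome selects zero variables")
    X = np.asarray(X, float)[:, mask]
    y = np.asarray(labels, object)
    val = np.zeros(X.shape[0], bool)
    val[np.asarray(validation_index_set, int)] = True
    if val.sum() == 0:
        raise ValueError("validation set is empty")
    classes, means, Cinv = _class_stats(X[~val], y[~val])
    Xv, yv = X[val], y[val]
    # squared Mahalanobis distance of every validation row to every class mean
    M = np.stack([means[c] for c in classes])           # (K, d)
    D = Xv[:, None, :] - M[None, :, :]                  # (nv, K, d)
    r2 = np.einsum("nkd,de,nke->nk", D, Cinv, D)
    own_col = np.array([classes.index(c) for c in yv])
    rows = np.arange(Xv.shape[0])
    d_own = r2[rows, own_col]
    r2_wrong = r2.copy()
    r2_wrong[rows, own_col] = np.inf
    d_wrong = r2_wrong.min(axis=1)
    if np.any(d_wrong == 0.0):
        logger.warning("validation sample coincides with a wrong-class mean; gn = inf")
    with np.errstate(divide="ignore"):
        gs = np.where(d_wrong == 0.0, np.inf, np.maximum(d_own, 0.0) / d_wrong)
    return float(np.mean(gs))


def _fitness(mask, X, y, fold_ids) -> float:
    """1 / mean cost over the internal folds, capped on degenerate separation."""
    gtot = 0.0
    for f in np.unique(fold_ids):
        gtot += cost_G(mask, X, y, np.where(fold_ids == f)[0])
    g = gtot / len(np.unique(fold_ids))
    if g < 1e-12:
        logger.warning("cost G underflow (perfect separation); fitness capped")
        return _FITNESS_CAP
    return 1.0 / g


def _repair(mask: np.ndarray, lo: int, hi: int, rng: np.random.Generator) -> np.ndarray:
    pc = int(mask.sum())
    if pc < lo:
        off = np.where(~mask)[0]
        add = rng.choice(off, size=lo - pc, replace=False)
        mask[add] = True
    elif pc > hi:
        on = np.where(mask)[0]
        drop = rng.choice(on, size=pc - hi, replace=False)
        mask[drop] = False
    return mask


def run_ga(X: np.ndarray, labels, config: GAConfig) -> GARun:
    """Evolve wavenumber-selection chromosomes; returns the best mask and the
    per-generation best-fitness history (non-decreasing under elitism >= 1).

    The validation rows for the cost come from an internal Venetian-blinds
    split (``config.cost_folds``) of the supplied rows, averaged over folds —
    the held-out test set never influences selection.
    """
    X = np.asarray(X, float)
    y = np.asarray(labels, object)
    n, m = X.shape
    if config.max_features > m:
        raise ValueError("max_features exceeds number of variables")
    if config.max_features >= n - len(set(y.tolist())):
        logger.warning(
            "max_features (%d) close to sample count (%d); covariance will be ridge-stabilized",
            config.max_features, n,
        )
    rng = np.random.default_rng(config.seed)
    fold_ids = np.arange(n) % min(config.cost_folds, n)
    pop = np.zeros((config.population_size, m), bool)
    for i in range(config.population_size):
        k = int(rng.integers(config.min_features, config.max_features + 1))
        pop[i, rng.choice(m, size=k, replace=False)] = True
    history = np.empty(config.generations)
    best_mask = None
    best_fit = -np.inf
    fits = np.array([_fitness(c, X, y, fold_ids) for c in pop])
    for gen in range(config.generations):
        gi = int(np.argmax(fits))
        if fits[gi] > best_fit:
            best_fit = float(fits[gi])
            best_mask = pop[gi].copy()
        history[gen] = float(fits[gi])  # generation best; non-decreasing under elitism
        if gen == config.generations - 1:
            break
        elite_idx = np.argsort(fits)[::-1][: config.elitism_count]
        children = [pop[j].copy() for j in elite_idx]
        while len(children) < config.population_size:
            # tournament selection, size 2
            parents = []
            for _ in range(2):
                a, b = rng.integers(0, config.population_size, size=2)
                parents.append(pop[a] if fits[a] >= fits[b] else pop[b])
            c1, c2 = parents[0].copy(), parents[1].copy()
            if rng.random() < config.p_crossover and m > 1:
                pt = int(rng.integers(1, m))
                c1 = np.concatenate([parents[0][:pt], parents[1][pt:]])
                c2 = np.concatenate([parents[1][:pt], parents[0][pt:]])
            for c in (c1, c2):
                rate = config.p_mutation * max(int(c.sum()), 1) / m
                flip = rng.random(m) < rate
                c ^= flip
                c = _repair(c, config.min_features, config.max_features, rng)
                children.append(c)
        pop = np.array(children[: config.population_size])
        fits = np.array([_fitness(c, X, y, fold_ids) for c in pop])
    return GARun(best_chromosome=best_mask, best_fitness_history=history, seed=config.seed)


def ga_lda_classify(
    X_train: np.ndarray,
    labels,
    X_test: np.ndarray,
    config: GAConfig,
    wavenumbers: np.ndarray | None = None,
):
    """GA-LDA: select variables on the training rows, fit pooled-covariance
    LDA on them, predict the test rows by minimum Mahalanobis distance.

    Returns (predicted labels, distance matrix, selected wavenumbers-or-indices,
    GARun, fitted LDAModel).
    """
    run = run_ga(X_train, labels, config)
    idx = run.selected_indices
    lda = fit_lda(np.asarray(X_train, float)[:, idx], labels)
    from .classify import lda_distances

    Xt = np.atleast_2d(np.asarray(X_test, float))[:, idx]
    dists = lda_distances(lda, Xt)
    pred = lda_predict(lda, Xt)
    selected = idx if wavenumbers is None else np.asarray(wavenumbers, float)[idx]
    return pred, dists, selected, run, lda


class GALDA:
    """GA-selected-variable LDA in the Model/Results style.

    The GA runs once on the training rows; the results object carries the
    selected variable indices (and wavenumbers when an axis is supplied), the
    fitness history and the fitted LDA.
    """

    def __init__(self, X, y, config: GAConfig | None = None, wavenumbers=None):
        self.X = np.asarray(X, float)
        self.y = np.asarray(y, object)
        self.config = config if config is not None else GAConfig()
        self.wavenumbers = None if wavenumbers is None else np.asarray(wavenumbers, float)

    def fit(self) -> "GALDAResults":
        run = run_ga(self.X, self.y, self.config)
        idx = run.selected_indices
        lda = fit_lda(self.X[:, idx], self.y)
        return GALDAResults(self, run, lda)


class GALDAResults:
    def __init__(self, model: GALDA, run: GARun, lda: LDAModel):
        self.model = model
        self.run = run
        self.lda = lda

    @property
    def selected_indices(self) -> np.ndarray:
        return self.run.selected_indices

    @property
    def selected_wavenumbers(self) -> np.ndarray | None:
        if self.model.wavenumbers is None:
            return None
        return self.model.wavenumbers[self.selected_indices]

    def predict(self, X):
        Xs = np.atleast_2d(np.asarray(X, float))[:, self.selected_indices]
        return lda_predict(self.lda, Xs)

    def decision_scores(self, X):
        from .classify import lda_distances

        Xs = np.atleast_2d(np.asarray(X, float))[:, self.selected_indices]
        L = lda_distances(self.lda, Xs)
        return L[:, 0] - L[:, -1]

    def summary(self) -> str:
        return (
            f"GALDAResults\n  classes: {self.lda.class_list}\n"
            f"  selected variables: {self.selected_indices.size}\n"
            f"  final fitness: {self.run.best_fitness_history[-1]:.4g}"
        )
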