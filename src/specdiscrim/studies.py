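"""Seeded validation studies run against planted ground truth.

These are the package's own calibration experiments: they synthesize data
with known discriminative structure, run the full method, and measure how
often the structure is recovered.  Problem sizes are fixed here once and
documented in the methods note.
"""

from __future__ import annotations

import numpy as np

from .classify import PLSDA
from .cohort import CohortSpec, generate_tissue_cohort, planted_truth
from .data import build_class_labels, mean_spectrum
from .decomposition import top_peaks
from .ga import GAConfig, run_ga
from .metrics import evaluate_protocol
from .preprocess import PreprocessConfig, preprocess

__all__ = [
    "plsda_peak_recovery",
    "ga_recovery_trial",
    "ga_recovery_study",
    "null_cv_study",
]


def _preprocessed_scheme(spec: CohortSpec, scheme: str):
    sset, meta, truth = generate_tissue_cohort(spec)
    total = sset.with_labels(build_class_labels(meta, scheme))
    means = mean_spectrum(total)
    tr, te, _ = preprocess(PreprocessConfig(), total, means)
    return tr, te, total, means, truth


def plsda_peak_recovery(
    seed: int, scheme: str = "necrotising", n_lv: int = 3,
    tolerance_cm1: float = 5.0, extra_peaks: int = 2,
) -> bool:
    """One trial: are all planted centers within +-tolerance of a top
    PLS-DA coefficient peak on a high-SNR synthetic tissue cohort?

    ``extra_peaks`` peaks beyond the planted count are allowed in the top
    list: on unit-norm derivative spectra an amplitude effect at one band
    necessarily induces compensating coefficient structure elsewhere
    (closure), so the planted bands need not be exactly the top-k.
    """
    spec = CohortSpec.tissue_high_snr(seed=seed)
    tr, _, _, _, truth = _preprocessed_scheme(spec, scheme)
    res = PLSDA(tr.intensities, tr.labels, n_lv=n_lv).fit()
    planted = planted_truth(truth, scheme)
    peaks = top_peaks(
        res.coefficients, tr.wavenumbers,
        k=len(planted) + extra_peaks, min_separation_cm1=20.0,
    )
    return all(any(abs(p - c) <= tolerance_cm1 for p in peaks) for c in planted)


def ga_recovery_trial(
    seed: int, n: int = 160, m: int = 500, n_planted: int = 5,
    delta: float = 3.0, population_size: int = 100, generations: int = 40,
    max_features: int = 12, permute_labels: bool = False,
) -> int:
    """One GA recovery trial on a two-class matrix with ``n_planted`` mean-
    shifted variables (shift ``delta`` in within-class sd units); returns how
    many planted variables the best chromosome contains.

    ``permute_labels=True`` runs the matched null (labels shuffled), under
    which recovery falls to the hypergeometric chance level.
    """
    rng = np.random.default_rng(100_000 + seed)
    X = rng.normal(size=(n, m))
    y = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2), dtype=object)
    idx = rng.choice(m, size=n_planted, replace=False)
    X[np.where(y == "B")[0][:, None], idx] += delta
    if permute_labels:
        y = rng.permutation(y)
    cfg = GAConfig(
        population_size=population_size, generations=generations,
        min_features=n_planted, max_features=max_features, seed=seed,
    )
    run = run_ga(X, y, cfg)
    return len(set(idx.tolist()) & set(run.selected_indices.tolist()))


def ga_recovery_study(
    n_seeds: int = 20, threshold: int = 4, seed0: int = 0, **kwargs
) -> float:
    """Fraction of seeded trials recovering >= ``threshold`` planted variables."""
    hits = [ga_recovery_trial(seed0 + i, **kwargs) for i in range(n_seeds)]
    return float(np.mean([h >= threshold for h in hits]))


def null_cv_study(
    n_seeds: int = 10, scheme: str = "necrotising", n_lv: int = 3, k: int = 10,
    seed0: int = 0,
) -> tuple[float, float]:
    """Mean CV accuracy (%) and mean honest held-out test accuracy (%) of
    PLS-DA on zero-effect cohorts: both should sit at chance."""
    cv_accs, test_accs = [], []
    for seed in range(seed0, seed0 + n_seeds):
        spec = CohortSpec.zero_effect("tissue", seed=seed)
        tr, te, total, means, _ = _preprocessed_scheme(spec, scheme)
        factory = lambda X, y: PLSDA(X, y, n_lv=n_lv).fit()  # noqa: E731
        res = evaluate_protocol(
            factory, tr.intensities, total.labels, total.sample_ids,
            te.intensities, te.labels, "present", cv="venetian", k=k,
        )
        cv_accs.append(res.cv.accuracy)
        held = list(dict.fromkeys(total.sample_ids.tolist()))[::3]
        res_h = evaluate_protocol(
            factory, tr.intensities, total.labels, total.sample_ids,
            te.intensities, te.labels, "present", cv="venetian",
            k=min(k, 12), holdout_samples=held,
        )
        test_accs.append(res_h.test.accuracy)
    return float(np.mean(cv_accs)), float(np.mean(test_accs))
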