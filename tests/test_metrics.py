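import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specdiscrim.classify import PLSDA
from specdiscrim.metrics import (
    ConfusionCounts,
    confusion,
    evaluate_protocol,
    loo_folds,
    metrics_from_counts,
    metrics_from_rates,
    roc_auc,
    round_half_away,
    venetian_folds,
)


class TestFolds:
    def test_venetian_definition(self):
        np.testing.assert_array_equal(venetian_folds(6, 3).fold, [0, 1, 2, 0, 1, 2])

    def test_k_equal_n_is_loo(self):
        f = venetian_folds(5, 5)
        assert sorted(f.fold.tolist()) == [0, 1, 2, 3, 4]
        np.testing.assert_array_equal(f.fold, loo_folds(5).fold)

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            venetian_folds(5, 6)

    def test_folds_nonempty_at_k_n_minus_one(self):
        f = venetian_folds(10, 9)
        assert np.bincount(f.fold, minlength=9).min() >= 1


class TestConfusion:
    def test_all_correct(self):
        c = confusion(["p", "n", "p"], ["p", "n", "p"], "p")
        assert (c.TP, c.FP, c.TN, c.FN) == (2, 0, 1, 0)

    def test_all_flipped(self):
        c = confusion(["p", "n"], ["n", "p"], "p")
        assert (c.TP, c.TN) == (0, 0) and (c.FP, c.FN) == (1, 1)

    def test_hand_counts_five_samples(self):
        c = confusion(["p", "p", "n", "n", "n"], ["p", "n", "p", "n", "n"], "p")
        assert (c.TP, c.FN, c.FP, c.TN) == (1, 1, 1, 2)
        assert c.n == 5


class TestMetricScores:
    def test_rounding_half_away_from_zero(self):
        assert round_half_away(94.5) == 95
        assert round_half_away(69.496) == 69
        assert round_half_away(-0.5) == -1

    @pytest.mark.parametrize(
        "sens,spec,fs,gs",
        [
            (100, 90, 95, 95),
            (58, 71, 64, 64),
            (100, 100, 100, 100),
            (100, 73, 84, 85),
            (57, 70, 63, 63),
            (0, 80, 0, 0),
        ],
    )
    def test_f_and_g_scores_from_rates(self, sens, spec, fs, gs):
        f, g = metrics_from_rates(sens, spec)
        assert round_half_away(f) == fs
        assert round_half_away(g) == gs

    def test_literal_g_form_kept_for_comparison(self):
        _, g = metrics_from_rates(58, 71, literal_g=True)
        assert g == pytest.approx(41.18)

    def test_counts_example(self):
        # 7 positives all found, 18/20 negatives correct
        rep = metrics_from_counts(ConfusionCounts(TP=7, FP=2, TN=18, FN=0))
        r = rep.rounded()
        assert (r["accuracy"], r["sensitivity"], r["specificity"]) == (93, 100, 90)
        assert (r["f_score"], r["g_score"]) == (95, 95)

    def test_missing_sensitivity_flagged_not_zero(self):
        rep = metrics_from_counts(ConfusionCounts(TP=0, FP=1, TN=4, FN=0))
        assert rep.sensitivity is None
        assert rep.f_score is None

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_counts(ConfusionCounts(0, 0, 0, 0))


def auc_pair_counting(scores, labels, positive):
    """Mann-Whitney pair-counting oracle: ties count one half."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], ["n", "n", "p", "p"], "p")
        assert auc == 1.0

    def test_all_tied_scores(self):
        _, auc = roc_auc([0.5] * 6, ["n", "p"] * 3, "p")
        assert auc == 0.5

    @given(
        st.lists(st.integers(0, 5), min_size=8, max_size=10),
        st.integers(1, 7),
    )
    @settings(max_examples=50, deadline=None)
    def test_equals_pair_counting_oracle(self, scores, n_pos):
        n_pos = min(n_pos, len(scores) - 1)
        labels = ["p"] * n_pos + ["n"] * (len(scores) - n_pos)
        _, auc = roc_auc(np.asarray(scores, float), labels, "p")
        assert auc == pytest.approx(auc_pair_counting(scores, labels, "p"), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=12)
        labels = ["p"] * 5 + ["n"] * 7
        _, a1 = roc_auc(scores, labels, "p")
        _, a2 = roc_auc(np.exp(3 * scores) + 7, labels, "p")
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], ["p", "p"], "p")


class TestEvaluateProtocol:
    def plsda_factory(self, n_lv=3):
        return lambda X, y: PLSDA(X, y, n_lv=n_lv).fit()

    def test_high_effect_blind_test_f_score(self, necrotising_preprocessed):
        tr, te, total, means, _ = necrotising_preprocessed
        res = evaluate_protocol(
            self.plsda_factory(), tr.intensities, total.labels, total.sample_ids,
            te.intensities, te.labels, "present", cv="venetian", k=10,
        )
        assert res.test.f_score >= 95.0
        assert res.training.accuracy >= res.cv.accuracy

    def test_replicates_share_folds(self, necrotising_preprocessed):
        from specdiscrim.metrics import _sample_level_folds

        _, _, total, _, _ = necrotising_preprocessed
        folds = _sample_level_folds(total.sample_ids, 10)
        for s in set(total.sample_ids.tolist()):
            assert len(set(folds[total.sample_ids == s])) == 1

    def test_loo_cv_scheme_runs(self, necrotising_preprocessed):
        tr, te, total, means, _ = necrotising_preprocessed
        res = evaluate_protocol(
            self.plsda_factory(), tr.intensities, total.labels, total.sample_ids,
            te.intensities, te.labels, "present", cv="loo",
        )
        assert res.cv.n == 81

    def test_summary_has_three_blocks(self, necrotising_preprocessed):
        tr, te, total, means, _ = necrotising_preprocessed
        res = evaluate_protocol(
            self.plsda_factory(), tr.intensities, total.labels, total.sample_ids,
            te.intensities, te.labels, "present",
        )
        df = res.summary()
        assert list(df["spectral_data"]) == ["Training: TPS", "CV: TPS", "Test: MPS"]

    def test_training_not_worse_than_cv_on_average(self):
        """Resubstitution optimism: over seeds, Training accuracy >= CV."""
        from specdiscrim.cohort import CohortSpec, generate_tissue_cohort
        from specdiscrim.data import build_class_labels, mean_spectrum
        from specdiscrim.preprocess import PreprocessConfig, preprocess

        diffs = []
        for seed in range(8):
            spec = CohortSpec.tissue_default(seed=seed, effect_multiplier=1.15)
            sset, meta, _ = generate_tissue_cohort(spec)
            total = sset.with_labels(build_class_labels(meta, "necrotising"))
            means = mean_spectrum(total)
            tr, te, _ = preprocess(PreprocessConfig(), total, means)
            res = evaluate_protocol(
                self.plsda_factory(), tr.intensities, total.labels, total.sample_ids,
                te.intensities, te.labels, "present", cv="venetian", k=10,
            )
            diffs.append(res.training.accuracy - res.cv.accuracy)
        assert np.mean(diffs) >= 0.0

    def test_holdout_mode_excludes_samples_from_training(self, necrotising_preprocessed):
        tr, te, total, means, _ = necrotising_preprocessed
        held = list(dict.fromkeys(total.sample_ids.tolist()))[::3]
        res = evaluate_protocol(
            self.plsda_factory(), tr.intensities, total.labels, total.sample_ids,
            te.intensities, te.labels, "present", cv="venetian", k=9,
            holdout_samples=held,
        )
        assert res.test.n == len(held)
        assert res.training.n == 81 - 3 * len(held)
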