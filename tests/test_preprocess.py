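import numpy as np
import pytest

from specdiscrim.data import SpectrumSet
from specdiscrim.preprocess import (
    PreprocessConfig,
    apply_center,
    cut_region,
    fit_center,
    preprocess,
    sg_derivative,
    vector_normalize,
)


def make_set(X, axis=None):
    X = np.atleast_2d(np.asarray(X, float))
    axis = np.arange(X.shape[1], dtype=float) if axis is None else np.asarray(axis, float)
    return SpectrumSet(
        wavenumbers=axis,
        intensities=X,
        spectrum_ids=np.array([f"s{i}" for i in range(X.shape[0])], object),
        sample_ids=np.array([f"s{i}" for i in range(X.shape[0])], object),
    )


def sg_oracle(y, x, window, polyorder, deriv):
    """Pointwise local least-squares polynomial fit, evaluated off-centre at
    the edges — independent of scipy's filter implementation."""
    m = len(y)
    h = window // 2
    out = np.empty(m)
    from math import factorial

    for i in range(m):
        start = min(max(i - h, 0), m - window)
        xs = x[start : start + window] - x[i]
        coef = np.polynomial.polynomial.polyfit(xs, y[start : start + window], polyorder)
        out[i] = coef[deriv] * factorial(deriv)
    return out


class TestCutRegion:
    def test_inclusive_point_count(self):
        s = make_set(np.ones((1, 1601)), axis=400.0 + np.arange(1601))
        out = cut_region(s, 800, 1800)
        assert out.n_points == 1001
        assert out.wavenumbers[0] == 800 and out.wavenumbers[-1] == 1800

    def test_full_range_is_identity(self):
        s = make_set(np.random.default_rng(0).normal(size=(2, 50)))
        out = cut_region(s, s.wavenumbers[0], s.wavenumbers[-1])
        np.testing.assert_array_equal(out.intensities, s.intensities)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            cut_region(make_set(np.ones((1, 10))), 9, 1)


class TestSavitzkyGolay:
    def test_exact_on_quadratic(self):
        x = np.arange(80.0)
        s = make_set(x**2, axis=x)
        out = sg_derivative(s, window=11, polyorder=2, deriv=2)
        np.testing.assert_allclose(out.intensities[0], 2.0, atol=1e-9)

    def test_constant_gives_zero(self):
        out = sg_derivative(make_set(np.full((1, 60), 7.0)), 11, 2, 2)
        np.testing.assert_allclose(out.intensities[0], 0.0, atol=1e-12)

    def test_offset_invariance_exact(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=60)
        a = sg_derivative(make_set(y), 11, 2, 2).intensities[0]
        b = sg_derivative(make_set(y + 123.4), 11, 2, 2).intensities[0]
        np.testing.assert_allclose(a, b, atol=1e-10)

    @pytest.mark.parametrize("polyorder,deriv", [(2, 2), (2, 1), (3, 2)])
    def test_matches_brute_force_polyfit_oracle(self, polyorder, deriv):
        rng = np.random.default_rng(7)
        x = 400.0 + np.arange(80.0)
        y = rng.normal(size=80)
        ours = sg_derivative(make_set(y, axis=x), 11, polyorder, deriv).intensities[0]
        np.testing.assert_allclose(ours, sg_oracle(y, x, 11, polyorder, deriv), atol=1e-9)

    def test_spacing_scaling(self):
        # second derivative of x^2 is 2 regardless of grid spacing
        x = np.arange(0, 40, 0.5)
        out = sg_derivative(make_set(x**2, axis=x), 11, 2, 2)
        np.testing.assert_allclose(out.intensities[0], 2.0, atol=1e-8)

    def test_non_uniform_axis_rejected(self):
        axis = np.concatenate([np.arange(30.0), [30.5, 32.0, 34.0]])
        with pytest.raises(ValueError, match="resample"):
            sg_derivative(make_set(np.ones((1, 33)), axis=axis), 11, 2, 2)


class TestVectorNormalize:
    def test_three_four_five(self):
        out = vector_normalize(make_set([[3.0, 4.0]]))
        np.testing.assert_allclose(out.intensities[0], [0.6, 0.8])

    def test_scale_invariance(self):
        y = np.random.default_rng(1).normal(size=(1, 20))
        a = vector_normalize(make_set(y)).intensities
        b = vector_normalize(make_set(5.0 * y)).intensities
        np.testing.assert_allclose(a, b, atol=1e-15)

    def test_zero_row_names_spectrum(self):
        with pytest.raises(ValueError, match="s0"):
            vector_normalize(make_set(np.zeros((1, 5))))


class TestCentering:
    def test_train_columns_zero_mean(self):
        s = make_set(np.random.default_rng(2).normal(size=(4, 6)))
        c = fit_center(s)
        out = apply_center(c, s)
        np.testing.assert_allclose(out.intensities.mean(axis=0), 0.0, atol=1e-12)

    def test_test_row_uses_train_means(self):
        train = make_set([[0.0, 0.0], [2.0, 4.0]])
        c = fit_center(train)
        t = make_set([[10.0, 10.0]])
        out = apply_center(c, t)
        np.testing.assert_allclose(out.intensities[0], [9.0, 8.0])

    def test_add_back_means_inverts(self):
        s = make_set(np.random.default_rng(4).normal(size=(3, 5)))
        c = fit_center(s)
        back = apply_center(c, s).intensities + c.column_means
        np.testing.assert_allclose(back, s.intensities, atol=1e-14)

    def test_length_mismatch_rejected(self):
        c = fit_center(make_set(np.ones((2, 4))))
        with pytest.raises(ValueError, match="length"):
            apply_center(c, make_set(np.ones((1, 5))))


class TestChain:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            PreprocessConfig(cut_low=1800, cut_high=800)
        with pytest.raises(ValueError):
            PreprocessConfig(sg_window=10)
        with pytest.raises(ValueError):
            PreprocessConfig(sg_deriv=3, sg_polyorder=2)

    def test_stage_gating(self):
        s = make_set(
            np.random.default_rng(6).normal(size=(3, 200)) + 10,
            axis=800.0 + np.arange(200),
        )
        cfg = PreprocessConfig(cut_low=800, cut_high=999, normalize=False, center=False)
        out, _, centerer = preprocess(cfg, s)
        assert centerer is None
        # equals cut + SG only
        manual = sg_derivative(cut_region(s, 800, 999), 51, 2, 2)
        np.testing.assert_array_equal(out.intensities, manual.intensities)

    def test_norms_and_centering_in_full_chain(self, necrotising_preprocessed):
        tr, _, total, _, _ = necrotising_preprocessed
        np.testing.assert_allclose(tr.intensities.mean(axis=0), 0.0, atol=1e-12)
        cfg = PreprocessConfig(center=False)
        uncentered, _, _ = preprocess(cfg, total)
        np.testing.assert_allclose(
            np.linalg.norm(uncentered.intensities, axis=1), 1.0, atol=1e-12
        )

    def test_deterministic_bit_identical(self, necrotising_preprocessed):
        _, _, total, _, _ = necrotising_preprocessed
        a, _, _ = preprocess(PreprocessConfig(), total)
        b, _, _ = preprocess(PreprocessConfig(), total)
        assert np.array_equal(a.intensities, b.intensities)

    def test_multiplicative_gain_removed(self):
        rng = np.random.default_rng(9)
        axis = 400.0 + np.arange(1201)
        y = np.exp(-0.5 * ((axis - 900) / 30.0) ** 2) + 0.3
        gains = np.array([[1.0], [2.5], [0.2]])
        s = make_set(gains * y, axis=axis)
        cfg = PreprocessConfig(center=False)
        out, _, _ = preprocess(cfg, s)
        np.testing.assert_allclose(out.intensities[1], out.intensities[0], atol=1e-12)
        np.testing.assert_allclose(out.intensities[2], out.intensities[0], atol=1e-12)
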