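"""Spectral preprocessing chain: cut, Savitzky-Golay derivative, vector
normalization, train-fitted mean-centering.

The chain is applied in that fixed order.  The second-derivative filter
removes slowly varying fluorescence baseline (any constant or low-order
polynomial background vanishes exactly); unit-norm scaling removes the
multiplicative intensity differences between samples (laser focus, section
thickness); mean-centering is fitted on the training spectra only and the
stored column means are subtracted from any later set, so the test transform
never sees test statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .data import SpectrumSet

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "FittedCenterer",
    "cut_region",
    "sg_derivative",
    "vector_normalize",
    "fit_center",
    "apply_center",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    Defaults: retain 800-1800 cm^-1 (closed interval), 2nd-order SG
    derivative with a 51-point window and 2nd-order polynomial, unit
    Euclidean normalization, train-fitted mean-centering.
    """

    cut_low: float = 800.0
    cut_high: float = 1800.0
    sg_window: int = 51
    sg_polyorder: int = 2
    sg_deriv: int = 2
    normalize: bool = True
    center: bool = True
    #: 'train' fits column means on training spectra only; 'pooled' fits on
    #: train+test jointly (fidelity experiments only -- leaks test statistics).
    center_on: str = "train"

    def __post_init__(self):
        if not self.cut_low < self.cut_high:
            raise ValueError("cut_low must be < cut_high")
        if self.sg_window % 2 != 1 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and > sg_polyorder")
        if self.sg_deriv > self.sg_polyorder:
            raise ValueError("sg_deriv must be <= sg_polyorder")
        if self.center_on not in ("train", "pooled"):
            raise ValueError("center_on must be 'train' or 'pooled'")


@dataclass(frozen=True)
class FittedCenterer:
    """Column means learned on a training set, in derivative-intensity units."""

    column_means: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "column_means", np.asarray(self.column_means, float))


def cut_region(sset: SpectrumSet, cut_low: float, cut_high: float) -> SpectrumSet:
    """Retain axis points in the closed interval [cut_low, cut_high]."""
    if not cut_low < cut_high:
        raise ValueError("cut_low must be < cut_high")
    mask = (sset.wavenumbers >= cut_low) & (sset.wavenumbers <= cut_high)
    if mask.sum() < 2:
        raise ValueError(
            f"cut [{cut_low}, {cut_high}] retains {int(mask.sum())} points; need >= 2"
        )
    return sset.with_intensities(
        sset.intensities[:, mask], wavenumbers=sset.wavenumbers[mask]
    )


def sg_derivative(
    sset: SpectrumSet, window: int, polyorder: int, deriv: int
) -> SpectrumSet:
    """Savitzky-Golay derivative of each spectrum w.r.t. wavenumber.

    Requires a uniformly spaced axis (relative tolerance 1e-6).  Output values
    are scaled by the axis spacing to the power ``deriv`` (units per
    (cm^-1)^deriv).  Edges are handled by evaluating the local polynomial fit
    at off-centre positions, so the output length equals the input length.
    """
    w = sset.wavenumbers
    spacing = np.diff(w)
    d0 = spacing.mean()
    if not np.allclose(spacing, d0, rtol=1e-6, atol=0):
        raise ValueError(
            "non-uniform wavenumber spacing; resample onto a uniform grid before "
            "applying the Savitzky-Golay filter"
        )
    if window > sset.n_points:
        raise ValueError(f"SG window ({window}) exceeds axis length ({sset.n_points})")
    Y = savgol_filter(
        sset.intensities, window_length=window, polyorder=polyorder,
        deriv=deriv, delta=d0, axis=1, mode="interp",
    )
    return sset.with_intensities(Y)


def vector_normalize(sset: SpectrumSet) -> SpectrumSet:
    """Scale every spectrum to unit Euclidean norm."""
    norms = np.linalg.norm(sset.intensities, axis=1)
    zero = norms == 0
    if zero.any():
        bad = sset.spectrum_ids[zero][0]
        raise ValueError(f"cannot normalize zero spectrum {bad!r}")
    return sset.with_intensities(sset.intensities / norms[:, None])


def fit_center(train: SpectrumSet) -> FittedCenterer:
    return FittedCenterer(column_means=train.intensities.mean(axis=0))


def apply_center(centerer: FittedCenterer, sset: SpectrumSet) -> SpectrumSet:
    mu = centerer.column_means
    if mu.size != sset.n_points:
        raise ValueError(
            f"centerer length {mu.size} does not match axis length {sset.n_points}"
        )
    return sset.with_intensities(sset.intensities - mu)


def preprocess(
    config: PreprocessConfig,
    train: SpectrumSet,
    test: SpectrumSet | None = None,
) -> tuple[SpectrumSet, SpectrumSet | None, FittedCenterer | None]:
    """Run the full chain: cut -> SG derivative -> normalize -> center.

    The test set (typically the per-sample mean spectra) goes through the
    identical stages, except that centering uses the train-fitted column means
    (or pooled means when ``config.center_on == 'pooled'``).
    """

    def stages(s: SpectrumSet) -> SpectrumSet:
        s = cut_region(s, config.cut_low, config.cut_high)
        s = sg_derivative(s, config.sg_window, config.sg_polyorder, config.sg_deriv)
        if config.normalize:
            s = vector_normalize(s)
        return s

    tr = stages(train)
    te = stages(test) if test is not None else None
    centerer = None
    if config.center:
        if config.center_on == "pooled" and te is not None:
            pooled = np.vstack([tr.intensities, te.intensities])
            centerer = FittedCenterer(column_means=pooled.mean(axis=0))
            logger.warning("centering on pooled train+test data (fidelity mode)")
        else:
            centerer = fit_center(tr)
        tr = apply_center(centerer, tr)
        if te is not None:
            te = apply_center(centerer, te)
    return tr, te, centerer
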