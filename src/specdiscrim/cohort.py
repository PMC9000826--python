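"""Seeded generator of Raman-like tissue and urine cohorts with planted class
effects, providing ground truth for every pipeline stage.

A spectrum is built as

    intensity = gain * (baseline + sum of peak profiles) + Gaussian noise

on a 400-2000 cm^-1 axis at 1 cm^-1 resolution.  Peaks default to Lorentzian
line shapes (the typical Raman profile); the baseline is a cubic polynomial
plus one broad Gaussian hump emulating tissue fluorescence, so the
second-derivative preprocessing step demonstrably removes it.  The
multiplicative ``gain`` (lognormal across replicates) emulates the physical
intensity differences between acquisitions that vector normalization is meant
to cancel.

Class effects are amplitude multipliers on selected bands: samples positive
for a histological feature express the corresponding peaks more strongly
(more analyte, stronger band).  The default effect map plants

    tissue: necrotising lesions -> 1680, 1443, 1539 cm^-1
            IFTA (T1)           -> 891.92 cm^-1
            infiltrate          -> 1309, 1631, 1692 cm^-1
    urine:  necrotising lesions -> 1716, 1316, 800 cm^-1
            IFTA (T1)           -> 1247, 1175, 932, 1607 cm^-1
            infiltrate          -> 1458, 911 cm^-1

The default tissue cohort has 27 samples x 3 map-region spectra (81 spectra,
27 means); the default urine cohort 10 samples x 10 point spectra (100
spectra, 10 means), with the histological label frequencies of the cohorts
they emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import SampleMetadata, SpectrumSet, build_class_labels

__all__ = [
    "PeakSpec",
    "ClassEffect",
    "CohortSpec",
    "GroundTruth",
    "generate_spectrum",
    "generate_tissue_cohort",
    "generate_urine_cohort",
    "planted_truth",
    "TISSUE_EFFECTS",
    "URINE_EFFECTS",
]


@dataclass(frozen=True)
class PeakSpec:
    center: float          # cm^-1
    fwhm: float            # cm^-1
    amplitude: float       # arbitrary intensity units
    shape: str = "lorentzian"

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError("shape must be 'lorentzian' or 'gaussian'")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        """Unit-height line profile evaluated on the axis."""
        x = np.asarray(axis, float) - self.center
        hw = self.fwhm / 2.0
        if self.shape == "lorentzian":
            return hw**2 / (x**2 + hw**2)
        sigma = self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return np.exp(-0.5 * (x / sigma) ** 2)


@dataclass(frozen=True)
class ClassEffect:
    """Amplitude effect a positive class exerts on selected bands."""

    centers: tuple          # target peak centers, cm^-1
    multiplier: float = 1.6  # amplitude factor for positive samples
    center_shift: float = 0.0  # optional band shift, cm^-1

    def __post_init__(self):
        if self.multiplier <= 0:
            raise ValueError("multiplier must be > 0")


# Bands planted per histological scheme (see module docstring).
TISSUE_EFFECTS = {
    "necrotising": (1680.0, 1443.0, 1539.0),
    "ifta_T0_vs_T1": (891.92,),
    "infiltrate": (1309.0, 1631.0, 1692.0),
}
URINE_EFFECTS = {
    "necrotising": (1716.0, 1316.0, 800.0),
    "ifta_T0_vs_T1": (1247.0, 1175.0, 932.0, 1607.0),
    "infiltrate": (1458.0, 911.0),
}

# Base tissue template: protein/lipid/nucleic-acid bands common in renal
# tissue spectra; every planted effect center has a band here.
_TISSUE_PEAKS = (
    (622, 12, 0.15), (643, 12, 0.15), (720, 14, 0.20), (757, 12, 0.20),
    (828, 12, 0.25), (853, 12, 0.30), (878, 12, 0.20), (891.92, 12, 0.30),
    (937, 14, 0.25), (1003, 8, 0.90), (1031, 10, 0.40), (1093, 16, 0.30),
    (1126, 14, 0.30), (1208, 14, 0.20), (1247, 18, 0.40), (1309, 14, 0.35),
    (1340, 16, 0.35), (1443, 18, 0.50), (1539, 16, 0.35), (1585, 12, 0.20),
    (1618, 12, 0.25), (1631, 14, 0.30), (1655, 18, 0.90), (1680, 16, 0.35),
    (1692, 14, 0.25),
)

# Base urine template: urea-dominated with the planted marker bands present.
_URINE_PEAKS = (
    (680, 12, 0.30), (800, 14, 0.30), (911, 12, 0.25), (932, 12, 0.25),
    (1003, 8, 1.00), (1024, 12, 0.20), (1175, 14, 0.25), (1247, 16, 0.30),
    (1316, 14, 0.30), (1458, 16, 0.40), (1607, 12, 0.25), (1654, 18, 0.40),
    (1716, 16, 0.30),
)


def _default_peaks(table) -> tuple:
    return tuple(PeakSpec(c, w, a) for c, w, a in table)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cohort.

    ``effects`` maps a class scheme to a :class:`ClassEffect`; positive
    samples under that scheme have the listed bands' amplitudes multiplied.
    ``noise_sd`` is the per-point Gaussian noise, ``gain_sigma`` the lognormal
    sigma of the per-replicate multiplicative gain, and
    ``amplitude_jitter_sigma`` the lognormal sigma of per-sample per-peak
    biological amplitude variation.
    """

    specimen: str = "tissue"
    axis_start: float = 400.0
    axis_stop: float = 2000.0
    axis_step: float = 1.0
    replicates_per_sample: int = 3
    peaks: tuple = field(default_factory=lambda: _default_peaks(_TISSUE_PEAKS))
    effects: dict = field(default_factory=dict)
    baseline_poly: tuple = (2.0, 1.0, -0.8, 0.3)  # cubic in (w-start)/span
    hump_center: float = 1100.0
    hump_fwhm: float = 700.0
    hump_amplitude: float = 1.5
    noise_sd: float = 0.01
    gain_sigma: float = 0.2
    amplitude_jitter_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.replicates_per_sample < 1:
            raise ValueError("replicates_per_sample must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def axis(self) -> np.ndarray:
        n = int(round((self.axis_stop - self.axis_start) / self.axis_step)) + 1
        return self.axis_start + self.axis_step * np.arange(n)

    @classmethod
    def tissue_default(cls, seed: int = 0, effect_multiplier: float = 1.6) -> "CohortSpec":
        effects = {k: ClassEffect(v, effect_multiplier) for k, v in TISSUE_EFFECTS.items()}
        return cls(specimen="tissue", replicates_per_sample=3,
                   peaks=_default_peaks(_TISSUE_PEAKS), effects=effects, seed=seed)

    @classmethod
    def urine_default(cls, seed: int = 0, effect_multiplier: float = 1.6) -> "CohortSpec":
        effects = {k: ClassEffect(v, effect_multiplier) for k, v in URINE_EFFECTS.items()}
        return cls(specimen="urine", replicates_per_sample=10,
                   peaks=_default_peaks(_URINE_PEAKS), effects=effects, seed=seed)

    @classmethod
    def tissue_high_snr(cls, seed: int = 0) -> "CohortSpec":
        """High signal-to-noise variant used by recovery studies."""
        base = cls.tissue_default(seed=seed, effect_multiplier=2.5)
        return replace(base, noise_sd=0.005, amplitude_jitter_sigma=0.03)

    @classmethod
    def zero_effect(cls, specimen: str = "tissue", seed: int = 0) -> "CohortSpec":
        """Null cohort: identical class templates, noise only."""
        base = cls.tissue_default(seed=seed) if specimen == "tissue" else cls.urine_default(seed=seed)
        return replace(base, effects={k: ClassEffect(e.centers, 1.0)
                                      for k, e in base.effects.items()})

    def baseline(self) -> np.ndarray:
        w = self.axis
        u = (w - self.axis_start) / (self.axis_stop - self.axis_start)
        poly = sum(c * u**i for i, c in enumerate(self.baseline_poly))
        hump = self.hump_amplitude * PeakSpec(
            self.hump_center, self.hump_fwhm, 1.0, "gaussian"
        ).profile(w)
        return poly + hump


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: per-scheme labels, discriminative centers, effect sizes."""

    labels: dict            # scheme -> {sample_id: label}
    planted_centers: dict   # scheme -> tuple of cm^-1 centers
    effect_sizes: dict      # scheme -> amplitude multiplier


def generate_spectrum(
    peaks, baseline: np.ndarray, noise_sd: float, gain: float,
    rng: np.random.Generator, axis: np.ndarray,
) -> np.ndarray:
    """One spectrum: gain * (baseline + sum of peaks) + Gaussian noise."""
    signal = np.asarray(baseline, float).copy()
    for p in peaks:
        signal = signal + p.amplitude * p.profile(axis)
    noise = rng.normal(0.0, noise_sd, size=axis.size) if noise_sd > 0 else 0.0
    return gain * signal + noise


def _sample_peaks(spec: CohortSpec, row: pd.Series, rng: np.random.Generator) -> tuple:
    """Per-sample peak list: base amplitudes with biological jitter and the
    class-effect multipliers for every scheme the sample is positive under."""
    mult = np.ones(len(spec.peaks))
    shift = np.zeros(len(spec.peaks))
    for scheme, eff in spec.effects.items():
        if scheme == "ifta_T0_vs_T1":
            positive = row["ifta_grade"] == "T1"
        elif scheme == "normal_glomeruli_N0_vs_N1N2":
            positive = row["normal_glomeruli_grade"] != "N0"
        elif scheme == "berden_focal_vs_mixed":
            positive = row["berden"] == "mixed"
        else:
            positive = bool(row[scheme])
        if not positive:
            continue
        for c in eff.centers:
            for i, p in enumerate(spec.peaks):
                if abs(p.center - c) < 0.5:
                    mult[i] *= eff.multiplier
                    shift[i] += eff.center_shift
    jitter = rng.lognormal(0.0, spec.amplitude_jitter_sigma, size=len(spec.peaks))
    return tuple(
        PeakSpec(p.center + shift[i], p.fwhm, p.amplitude * mult[i] * jitter[i], p.shape)
        for i, p in enumerate(spec.peaks)
    )


def _generate_cohort(spec: CohortSpec, metadata: SampleMetadata) -> tuple:
    rng = np.random.default_rng(spec.seed)
    axis = spec.axis
    base = spec.baseline()
    rows, sids, samples, reps = [], [], [], []
    for _, row in metadata.table.iterrows():
        peaks = _sample_peaks(spec, row, rng)
        for r in range(spec.replicates_per_sample):
            gain = rng.lognormal(0.0, spec.gain_sigma) if spec.gain_sigma > 0 else 1.0
            rows.append(generate_spectrum(peaks, base, spec.noise_sd, gain, rng, axis))
            sids.append(f"{row['sample_id']}_r{r}")
            samples.append(row["sample_id"])
            reps.append(r)
    sset = SpectrumSet(
        wavenumbers=axis,
        intensities=np.vstack(rows),
        spectrum_ids=np.array(sids, object),
        sample_ids=np.array(samples, object),
        replicate_index=np.array(reps, int),
    )
    schemes = ("berden_focal_vs_mixed", "normal_glomeruli_N0_vs_N1N2",
               "ifta_T0_vs_T1", "necrotising", "infiltrate", "arteritis",
               "vessel_necrosis", "anca_status", "anca_serotype")
    truth = GroundTruth(
        labels={s: build_class_labels(metadata, s) for s in schemes},
        planted_centers={s: e.centers for s, e in spec.effects.items()},
        effect_sizes={s: e.multiplier for s, e in spec.effects.items()},
    )
    return sset, metadata, truth


def _assign(rng: np.random.Generator, values: list) -> np.ndarray:
    return rng.permutation(np.array(values, object))


def tissue_metadata(seed: int = 0, n_prefix: str = "t") -> SampleMetadata:
    """27-sample tissue metadata with the emulated cohort's label frequencies:
    Berden 15 focal / 3 crescentic / 9 mixed; normal glomeruli 21/2/4
    (N0/N1/N2); IFTA 20 T0 / 7 T1; necrotising 16; infiltrate 10; arteritis 5;
    vessel-wall necrosis 4; ANCA 12 MPO / 12 PR3 / 3 negative.  Marginal
    counts are exact; the joint assignment is a seeded permutation."""
    rng = np.random.default_rng(seed)
    n = 27
    df = pd.DataFrame(
        {
            "sample_id": [f"{n_prefix}{i + 1:02d}" for i in range(n)],
            "specimen": "tissue",
            "berden": _assign(rng, ["focal"] * 15 + ["crescentic"] * 3 + ["mixed"] * 9),
            "normal_glomeruli_grade": _assign(rng, ["N0"] * 21 + ["N1"] * 2 + ["N2"] * 4),
            "ifta_grade": _assign(rng, ["T0"] * 20 + ["T1"] * 7),
            "necrotising": _assign(rng, [True] * 16 + [False] * 11),
            "infiltrate": _assign(rng, [True] * 10 + [False] * 17),
            "arteritis": _assign(rng, [True] * 5 + [False] * 22),
            "vessel_necrosis": _assign(rng, [True] * 4 + [False] * 23),
            "anca": _assign(rng, ["MPO"] * 12 + ["PR3"] * 12 + ["negative"] * 3),
        }
    )
    return SampleMetadata(df)


def urine_metadata(seed: int = 0, n_prefix: str = "u") -> SampleMetadata:
    """10-sample paired-urine metadata: Berden 5 focal / 4 mixed /
    1 crescentic; 7 N0 / 3 N2; 7 T0 / 3 T1; 3 necrotising; 3 infiltrate;
    2 arteritis; 2 vessel necrosis; ANCA 4 MPO / 5 PR3 / 1 negative."""
    rng = np.random.default_rng(seed)
    n = 10
    df = pd.DataFrame(
        {
            "sample_id": [f"{n_prefix}{i + 1:02d}" for i in range(n)],
            "specimen": "urine",
            "berden": _assign(rng, ["focal"] * 5 + ["mixed"] * 4 + ["crescentic"]),
            "normal_glomeruli_grade": _assign(rng, ["N0"] * 7 + ["N2"] * 3),
            "ifta_grade": _assign(rng, ["T0"] * 7 + ["T1"] * 3),
            "necrotising": _assign(rng, [True] * 3 + [False] * 7),
            "infiltrate": _assign(rng, [True] * 3 + [False] * 7),
            "arteritis": _assign(rng, [True] * 2 + [False] * 8),
            "vessel_necrosis": _assign(rng, [True] * 2 + [False] * 8),
            "anca": _assign(rng, ["MPO"] * 4 + ["PR3"] * 5 + ["negative"]),
        }
    )
    return SampleMetadata(df)


def generate_tissue_cohort(spec: CohortSpec | None = None):
    """Synthesize the tissue cohort (default 27 samples x 3 replicates = 81
    spectra).  Returns (SpectrumSet, SampleMetadata, GroundTruth)."""
    if spec is None:
        spec = CohortSpec.tissue_default()
    meta = tissue_metadata(seed=spec.seed)
    return _generate_cohort(spec, meta)


def generate_urine_cohort(spec: CohortSpec | None = None):
    """Synthesize the paired-urine cohort (default 10 samples x 10 points =
    100 spectra).  Returns (SpectrumSet, SampleMetadata, GroundTruth)."""
    if spec is None:
        spec = CohortSpec.urine_default()
    meta = urine_metadata(seed=spec.seed)
    return _generate_cohort(spec, meta)


def planted_truth(ground_truth: GroundTruth, scheme: str) -> list[float]:
    """The discriminative wavenumbers planted for one scheme ([] if none)."""
    return list(ground_truth.planted_centers.get(scheme, ()))
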