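"""Data model and I/O for Raman spectra, maps, and sample metadata.

A :class:`SpectrumSet` holds a shared wavenumber axis (cm^-1, strictly
increasing) together with an ``n x m`` intensity matrix, one row per recorded
spectrum, annotated with spectrum/sample identifiers and replicate indices.
Raman maps are 3-D cubes that unfold to 2-D spectrum sets for chemometric
modelling; per-sample mean spectra serve as the blind test set downstream.

Canonical on-disk carrier is CSV: wavenumber in the first column, one column
per spectrum with the spectrum id in the header; sample metadata lives in a
separate CSV keyed by ``sample_id``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralFormatError",
    "SpectrumSet",
    "RamanMap",
    "SampleMetadata",
    "read_spectra_table",
    "write_spectra_table",
    "unfold_map",
    "refold_map",
    "mean_spectrum",
    "build_class_labels",
    "CLASS_SCHEMES",
    "SCHEME_POSITIVE",
]


class SpectralFormatError(ValueError):
    """Malformed spectral table or metadata (ragged rows, bad cells, ...)."""


def _check_axis(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("wavenumber axis must be 1-D with at least 2 points")
    if not np.all(np.isfinite(values)):
        raise ValueError("wavenumber axis contains non-finite values")
    if not np.all(np.diff(values) > 0):
        raise ValueError("wavenumber axis must be strictly increasing")
    return values


@dataclass(frozen=True)
class SpectrumSet:
    """A set of spectra sharing one wavenumber axis.

    Parameters
    ----------
    wavenumbers : (m,) array, strictly increasing, cm^-1.
    intensities : (n, m) array, arbitrary intensity units.
    spectrum_ids : n unique strings.
    sample_ids : n strings linking each spectrum to a sample.
    replicate_index : n integers (position of the spectrum within its sample).
    labels : optional n-vector of class labels (object array) or None.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    spectrum_ids: np.ndarray
    sample_ids: np.ndarray
    replicate_index: np.ndarray = None  # type: ignore[assignment]
    labels: np.ndarray | None = None

    def __post_init__(self):
        axis = _check_axis(self.wavenumbers)
        X = np.asarray(self.intensities, dtype=float)
        if X.ndim != 2:
            raise ValueError("intensities must be a 2-D matrix")
        if X.shape[1] != axis.size:
            raise ValueError(
                f"intensity columns ({X.shape[1]}) != axis length ({axis.size})"
            )
        if not np.all(np.isfinite(X)):
            raise SpectralFormatError("intensity matrix contains missing/non-finite values")
        sids = np.asarray(self.spectrum_ids, dtype=object)
        if sids.size != X.shape[0]:
            raise ValueError("spectrum_ids length does not match row count")
        if len(set(sids.tolist())) != sids.size:
            dup = pd.Series(sids).value_counts()
            raise SpectralFormatError(
                f"duplicate spectrum ids: {dup[dup > 1].index.tolist()}"
            )
        samp = np.asarray(self.sample_ids, dtype=object)
        if samp.size != X.shape[0]:
            raise ValueError("sample_ids length does not match row count")
        rep = self.replicate_index
        if rep is None:
            rep = np.zeros(X.shape[0], dtype=int)
        rep = np.asarray(rep, dtype=int)
        if rep.size != X.shape[0]:
            raise ValueError("replicate_index length does not match row count")
        lab = self.labels
        if lab is not None:
            lab = np.asarray(lab, dtype=object)
            if lab.size != X.shape[0]:
                raise ValueError("labels length does not match row count")
        object.__setattr__(self, "wavenumbers", axis)
        object.__setattr__(self, "intensities", X)
        object.__setattr__(self, "spectrum_ids", sids)
        object.__setattr__(self, "sample_ids", samp)
        object.__setattr__(self, "replicate_index", rep)
        object.__setattr__(self, "labels", lab)

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.intensities.shape[1]

    def with_intensities(self, X: np.ndarray, wavenumbers: np.ndarray | None = None) -> "SpectrumSet":
        """Return a copy with a new intensity matrix (and optionally axis)."""
        return replace(
            self,
            intensities=X,
            wavenumbers=self.wavenumbers if wavenumbers is None else wavenumbers,
        )

    def select(self, row_mask) -> "SpectrumSet":
        idx = np.asarray(row_mask)
        return SpectrumSet(
            wavenumbers=self.wavenumbers,
            intensities=self.intensities[idx],
            spectrum_ids=self.spectrum_ids[idx],
            sample_ids=self.sample_ids[idx],
            replicate_index=self.replicate_index[idx],
            labels=None if self.labels is None else self.labels[idx],
        )

    def with_labels(self, label_map: Mapping[str, object]) -> "SpectrumSet":
        """Attach per-spectrum labels from a sample_id -> label mapping.

        Spectra whose sample is absent from the mapping are dropped (the
        scheme excludes them); the dropped count is logged.
        """
        keep = np.array([s in label_map for s in self.sample_ids])
        if not keep.all():
            logger.info("with_labels: excluding %d spectra outside the scheme", int((~keep).sum()))
        sub = self.select(keep)
        labels = np.array([label_map[s] for s in sub.sample_ids], dtype=object)
        return replace(sub, labels=labels)


@dataclass(frozen=True)
class RamanMap:
    """A Raman map: an ``nx x ny`` grid of spectra on a common axis."""

    nx: int
    ny: int
    wavenumbers: np.ndarray
    cube: np.ndarray  # (nx, ny, m)

    def __post_init__(self):
        axis = _check_axis(self.wavenumbers)
        cube = np.asarray(self.cube, dtype=float)
        if cube.shape != (self.nx, self.ny, axis.size):
            raise ValueError(
                f"cube shape {cube.shape} inconsistent with (nx={self.nx}, ny={self.ny}, m={axis.size})"
            )
        object.__setattr__(self, "wavenumbers", axis)
        object.__setattr__(self, "cube", cube)


def unfold_map(rmap: RamanMap, sample_id: str = "map") -> SpectrumSet:
    """Unfold a 3-D map cube into an ``(nx*ny) x m`` spectrum matrix.

    Row order is row-major over the grid: y varies fastest within x, i.e.
    rows (0,0), (0,1), ..., (0,ny-1), (1,0), ...  ``refold_map`` inverts this
    exactly.
    """
    n = rmap.nx * rmap.ny
    X = rmap.cube.reshape(n, rmap.wavenumbers.size)
    ids = np.array(
        [f"{sample_id}_x{i}_y{j}" for i in range(rmap.nx) for j in range(rmap.ny)],
        dtype=object,
    )
    return SpectrumSet(
        wavenumbers=rmap.wavenumbers,
        intensities=X,
        spectrum_ids=ids,
        sample_ids=np.array([sample_id] * n, dtype=object),
        replicate_index=np.arange(n),
    )


def refold_map(sset: SpectrumSet, nx: int, ny: int) -> RamanMap:
    """Inverse of :func:`unfold_map` for a set produced in row-major order."""
    if sset.n_spectra != nx * ny:
        raise ValueError(f"{sset.n_spectra} spectra cannot fold to {nx}x{ny}")
    cube = sset.intensities.reshape(nx, ny, sset.n_points)
    return RamanMap(nx=nx, ny=ny, wavenumbers=sset.wavenumbers, cube=cube)


# ---------------------------------------------------------------------------
# CSV I/O


def read_spectra_table(
    path,
    sample_map: Mapping[str, str] | None = None,
    replicate_map: Mapping[str, int] | None = None,
) -> SpectrumSet:
    """Read a CSV spectral table (wavenumber first column, one column/spectrum).

    The axis is sorted ascending (rows reordered if the file stores a
    descending axis).  ``sample_map`` maps spectrum id -> sample id; without
    it each spectrum is its own sample.
    """
    try:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as exc:
        raise SpectralFormatError(f"cannot parse spectral table {path}: {exc}") from exc
    if df.columns.duplicated().any():
        raise SpectralFormatError(
            f"duplicate spectrum ids in header: {df.columns[df.columns.duplicated()].tolist()}"
        )
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & ~df[col].isna()
        if bad.any():
            row = df.index[bad][0]
            raise SpectralFormatError(
                f"non-numeric cell in column {col!r} at wavenumber {row!r}"
            )
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise SpectralFormatError(f"missing cell in column {col!r} at wavenumber {row!r}")
        df[col] = vals
    try:
        axis = np.asarray(df.index, dtype=float)
    except (TypeError, ValueError) as exc:
        raise SpectralFormatError(f"non-numeric wavenumber column: {exc}") from exc
    order = np.argsort(axis)
    axis = axis[order]
    X = df.to_numpy(dtype=float).T[:, order]
    ids = np.asarray(df.columns, dtype=object)
    samples = np.array(
        [sample_map.get(str(i), str(i)) if sample_map else str(i) for i in ids],
        dtype=object,
    )
    reps = np.array(
        [replicate_map.get(str(i), 0) if replicate_map else 0 for i in ids], dtype=int
    )
    return SpectrumSet(axis, X, ids, samples, reps)


def write_spectra_table(sset: SpectrumSet, path) -> None:
    """Write the canonical CSV layout (full float precision)."""
    df = pd.DataFrame(
        sset.intensities.T, index=sset.wavenumbers, columns=sset.spectrum_ids
    )
    df.index.name = "wavenumber"
    df.to_csv(path, float_format="%.17g")


# ---------------------------------------------------------------------------
# Aggregation and labelling


def mean_spectrum(sset: SpectrumSet, group_by: str = "sample_id") -> SpectrumSet:
    """One arithmetic-mean spectrum per group (default: per sample).

    The output spectrum id is the group key; groups appear in order of first
    appearance in the input.
    """
    if group_by == "sample_id":
        keys = sset.sample_ids
    elif group_by == "spectrum_id":
        keys = sset.spectrum_ids
    elif group_by == "labels":
        if sset.labels is None:
            raise ValueError("set has no labels to group by")
        keys = sset.labels
    else:
        raise ValueError(f"unknown group field {group_by!r}")
    if sset.n_spectra == 0:
        raise ValueError("cannot aggregate an empty spectrum set")
    seen: dict = {}
    for k in keys:
        seen.setdefault(k, []).append(True)
    order = list(seen)
    means = np.vstack(
        [sset.intensities[np.asarray(keys == k)].mean(axis=0) for k in order]
    )
    label_out = None
    if sset.labels is not None and group_by == "sample_id":
        lab = {}
        for k, l in zip(keys, sset.labels):
            lab.setdefault(k, l)
        label_out = np.array([lab[k] for k in order], dtype=object)
    return SpectrumSet(
        wavenumbers=sset.wavenumbers,
        intensities=means,
        spectrum_ids=np.array(order, dtype=object),
        sample_ids=np.array(order, dtype=object),
        replicate_index=np.zeros(len(order), dtype=int),
        labels=label_out,
    )


_BERDEN = {"focal", "crescentic", "sclerotic", "mixed"}
_NGRADE = {"N0", "N1", "N2"}
_IFTA = {"T0", "T1"}
_ANCA = {"MPO", "PR3", "negative"}
_BOOL_FIELDS = ("necrotising", "infiltrate", "arteritis", "vessel_necrosis")


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample histological and serological annotations.

    One record per sample: specimen type, Berden class, normal-glomeruli grade
    (N0 >25%, N1 10-25%, N2 <10%), IFTA grade (T0 <=25%, T1 >25%), lesion
    presence flags and ANCA serotype.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.table.copy()
        required = {"sample_id", "specimen", "berden", "normal_glomeruli_grade",
                    "ifta_grade", "anca", *_BOOL_FIELDS}
        missing = required - set(df.columns)
        if missing:
            raise SpectralFormatError(f"metadata missing columns: {sorted(missing)}")
        if df["sample_id"].duplicated().any():
            raise SpectralFormatError("duplicate sample_id in metadata")
        checks = [
            ("specimen", {"tissue", "urine"}),
            ("berden", _BERDEN),
            ("normal_glomeruli_grade", _NGRADE),
            ("ifta_grade", _IFTA),
            ("anca", _ANCA),
        ]
        for col, allowed in checks:
            vals = df[col].dropna()
            bad = set(vals) - allowed
            if bad:
                raise SpectralFormatError(f"invalid {col} values: {sorted(map(str, bad))}")
        for col in _BOOL_FIELDS:
            df[col] = df[col].astype("boolean")
        df = df.set_index("sample_id", drop=False)
        object.__setattr__(self, "table", df)

    @classmethod
    def read_csv(cls, path) -> "SampleMetadata":
        return cls(pd.read_csv(path))

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()


CLASS_SCHEMES = (
    "berden_focal_vs_mixed",
    "normal_glomeruli_N0_vs_N1N2",
    "ifta_T0_vs_T1",
    "necrotising",
    "infiltrate",
    "arteritis",
    "vessel_necrosis",
    "anca_status",
    "anca_serotype",
)

#: Label treated as the positive ("lesion present"/diseased) class per scheme.
SCHEME_POSITIVE = {
    "berden_focal_vs_mixed": "mixed",
    "normal_glomeruli_N0_vs_N1N2": "N1N2",
    "ifta_T0_vs_T1": "T1",
    "necrotising": "present",
    "infiltrate": "present",
    "arteritis": "present",
    "vessel_necrosis": "present",
    "anca_status": "positive",
    "anca_serotype": "PR3",
}


def build_class_labels(metadata: SampleMetadata, scheme: str) -> dict[str, str]:
    """Binary class labels per sample under one experimental scheme.

    Samples that fall outside the scheme (e.g. crescentic biopsies under
    ``berden_focal_vs_mixed``, ANCA-negative samples under ``anca_serotype``)
    are excluded; the excluded count is logged.  A missing grade on a sample
    the scheme needs is an error naming the sample.
    """
    if scheme not in CLASS_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; valid: {CLASS_SCHEMES}")
    df = metadata.table
    labels: dict[str, str] = {}
    excluded = 0
    for sid, row in df.iterrows():
        if scheme == "berden_focal_vs_mixed":
            v = row["berden"]
            if pd.isna(v):
                raise ValueError(f"sample {sid!r} has no berden class")
            if v in ("focal", "mixed"):
                labels[sid] = v
            else:
                excluded += 1
        elif scheme == "normal_glomeruli_N0_vs_N1N2":
            v = row["normal_glomeruli_grade"]
            if pd.isna(v):
                raise ValueError(f"sample {sid!r} has no normal-glomeruli grade")
            labels[sid] = "N0" if v == "N0" else "N1N2"
        elif scheme == "ifta_T0_vs_T1":
            v = row["ifta_grade"]
            if pd.isna(v):
                raise ValueError(f"sample {sid!r} has no IFTA grade")
            labels[sid] = v
        elif scheme in _BOOL_FIELDS:
            v = row[scheme]
            if pd.isna(v):
                raise ValueError(f"sample {sid!r} has no {scheme} flag")
            labels[sid] = "present" if bool(v) else "absent"
        elif scheme == "anca_status":
            v = row["anca"]
            if pd.isna(v):
                raise ValueError(f"sample {sid!r} has no ANCA serotype")
            labels[sid] = "negative" if v == "negative" else "positive"
        elif scheme == "anca_serotype":
            v = row["anca"]
            if pd.isna(v):
                raise ValueError(f"sample {sid!r} has no ANCA serotype")
            if v == "negative":
                excluded += 1
            else:
                labels[sid] = v
    if excluded:
        logger.info("scheme %s: excluded %d samples outside the scheme", scheme, excluded)
    return labels
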