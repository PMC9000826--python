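"""Config-driven end-to-end experiment runs.

An experiment takes a cohort (read from CSV or synthesized), builds binary
class labels for one histological scheme, preprocesses all replicate spectra
(the training set) and the per-sample mean spectra (the blind test set) with
a train-fitted chain, fits the chosen discriminant model and evaluates it
under the Training / CV / Test protocol, writing a metrics table shaped like
the clinical report (one row per block), ROC points, the coefficient or
selected-variable table, and a run manifest (config hash, seed, versions)
from which the run is reconstructible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import PCALDA, PLSDA, RBFSVM
from .cohort import CohortSpec, generate_tissue_cohort, generate_urine_cohort
from .data import (
    SCHEME_POSITIVE,
    SampleMetadata,
    SpectrumSet,
    build_class_labels,
    mean_spectrum,
    read_spectra_table,
)
from .ga import GAConfig, GALDA
from .metrics import ProtocolResults, evaluate_protocol, roc_auc
from .preprocess import PreprocessConfig, preprocess

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_experiment", "run_paired_comparison", "reproduce_report"]

MODEL_NAMES = ("plsda", "pcalda", "galda", "svm")


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment: input source, scheme, preprocessing, model, CV, seed."""

    scheme: str
    model: str = "plsda"
    model_params: dict = field(default_factory=dict)
    input_spectra: str | None = None
    input_metadata: str | None = None
    simulate: dict | None = None  # CohortSpec-style keys; 'specimen' selects cohort
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cv: str = "venetian"
    cv_k: int = 10
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        has_files = self.input_spectra is not None
        has_sim = self.simulate is not None
        if has_files == has_sim:
            raise ValueError("exactly one input source: file paths or a simulate block")
        if has_files and self.input_metadata is None:
            raise ValueError("input_spectra requires input_metadata")
        if self.model not in MODEL_NAMES:
            raise ValueError(f"model must be one of {MODEL_NAMES}")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def canonical_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _load_cohort(config: ExperimentConfig):
    if config.simulate is not None:
        sim = dict(config.simulate)
        specimen = sim.pop("specimen", "tissue")
        effect = sim.pop("effect_multiplier", None)
        if specimen == "tissue":
            spec = CohortSpec.tissue_default(seed=config.seed) if effect is None else \
                CohortSpec.tissue_default(seed=config.seed, effect_multiplier=effect)
            gen = generate_tissue_cohort
        elif specimen == "urine":
            spec = CohortSpec.urine_default(seed=config.seed) if effect is None else \
                CohortSpec.urine_default(seed=config.seed, effect_multiplier=effect)
            gen = generate_urine_cohort
        else:
            raise ValueError(f"unknown specimen {specimen!r}")
        if sim:
            from dataclasses import replace

            spec = replace(spec, **sim)
        sset, meta, truth = gen(spec)
        return sset, meta
    sset = read_spectra_table(config.input_spectra)
    meta = SampleMetadata.read_csv(config.input_metadata)
    sample_of = {}
    for sid in meta.sample_ids:
        for spec_id in sset.spectrum_ids:
            if str(spec_id).startswith(str(sid)):
                sample_of[spec_id] = sid
    if sample_of:
        sset = SpectrumSet(
            sset.wavenumbers, sset.intensities, sset.spectrum_ids,
            np.array([sample_of.get(i, s) for i, s in zip(sset.spectrum_ids, sset.sample_ids)], object),
            sset.replicate_index,
        )
    return sset, meta


def make_model_factory(name: str, params: dict, wavenumbers=None, seed: int = 0):
    """Return a callable (X, y) -> fitted results for the evaluation protocol."""
    params = dict(params)

    if name == "plsda":
        n_lv = params.get("n_lv")
        if n_lv in (None, "loo"):
            n_lv = None
        return lambda X, y: PLSDA(X, y, n_lv=n_lv, max_lv=params.get("max_lv", 10)).fit()
    if name == "pcalda":
        return lambda X, y: PCALDA(
            X, y, n_pc=params.get("n_pc"),
            variance_threshold=params.get("variance_threshold", 0.95),
        ).fit()
    if name == "svm":
        return lambda X, y: RBFSVM(
            X, y, gamma=params.get("gamma", 1.0), C=params.get("C", 1.0),
            tune_C=params.get("tune_C", False),
        ).fit()
    if name == "galda":
        ga_keys = {f for f in GAConfig.__dataclass_fields__}
        cfg = GAConfig(**{k: v for k, v in params.items() if k in ga_keys} | {"seed": seed})
        return lambda X, y: GALDA(X, y, config=cfg, wavenumbers=wavenumbers).fit()
    raise ValueError(f"unknown model {name!r}")


def run_experiment(config: ExperimentConfig) -> ProtocolResults:
    """Execute one experiment; writes report files when ``config.outdir`` is set."""
    sset, meta = _load_cohort(config)
    logger.info("raw spectra: %d (%d samples)", sset.n_spectra, len(set(sset.sample_ids)))
    labels = build_class_labels(meta, config.scheme)
    classes = sorted(set(labels.values()), key=str)
    counts = {c: sum(1 for v in labels.values() if v == c) for c in classes}
    if len(classes) != 2 or min(counts.values()) < 2:
        raise ValueError(
            f"scheme {config.scheme!r} needs two classes with >= 2 samples each; got {counts}"
        )
    total = sset.with_labels(labels)
    means = mean_spectrum(total)
    logger.info("labelled spectra: %d; mean spectra: %d", total.n_spectra, means.n_spectra)
    tr, te, _ = preprocess(config.preprocess, total, means)
    logger.info("post-cut axis length: %d", tr.n_points)
    factory = make_model_factory(
        config.model, config.model_params, wavenumbers=tr.wavenumbers, seed=config.seed
    )
    positive = SCHEME_POSITIVE[config.scheme]
    from dataclasses import replace as _dc_replace

    results = _dc_replace(
        evaluate_protocol(
            factory, tr.intensities, total.labels, total.sample_ids,
            te.intensities, te.labels, positive, cv=config.cv, k=config.cv_k,
        ),
        scheme=config.scheme,
        model_name=config.model,
    )
    if config.outdir is not None:
        _write_reports(config, results, factory, tr, te, positive)
    return results


def _write_reports(config, results, factory, tr, te, positive) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results.summary().to_csv(out / "metrics.csv", index=False)
    fitted = factory(tr.intensities, tr.labels)
    curve, auc = roc_auc(fitted.decision_scores(tr.intensities), tr.labels, positive)
    with open(out / "roc.json", "w") as fh:
        json.dump({"points": curve.tolist(), "auc": auc}, fh, indent=1)
    if config.model == "plsda":
        coef = fitted.coefficients
        order = np.argsort(-np.abs(coef))
        rank = np.empty_like(order)
        rank[order] = np.arange(1, coef.size + 1)
        pd.DataFrame(
            {"wavenumber": tr.wavenumbers, "coefficient": coef, "rank": rank}
        ).to_csv(out / "coefficients.csv", index=False)
    if config.model == "galda":
        pd.DataFrame({"wavenumber": fitted.selected_wavenumbers}).to_csv(
            out / "selected_wavenumbers.csv", index=False
        )
    manifest = {
        "config": json.loads(config.canonical_json()),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": _versions(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def _versions() -> dict:
    import scipy
    import sklearn

    return {
        "specdiscrim": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }


def run_paired_comparison(
    config_tissue: ExperimentConfig, config_urine: ExperimentConfig,
    schemes=("ifta_T0_vs_T1", "necrotising", "infiltrate"),
) -> pd.DataFrame:
    """Evaluate the same schemes on a tissue and a paired urine cohort,
    emitting one combined table (scheme x specimen x block rows)."""
    from dataclasses import replace

    frames = []
    for scheme in schemes:
        for specimen, cfg in (("tissue", config_tissue), ("urine", config_urine)):
            res = run_experiment(replace(cfg, scheme=scheme, outdir=None))
            df = res.summary()
            df.insert(1, "specimen", specimen)
            frames.append(df)
    combined = pd.concat(frames, ignore_index=True)
    outdir = config_tissue.outdir
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        combined.to_csv(Path(outdir) / "paired_comparison.csv", index=False)
    return combined


def reproduce_report(
    layout: str = "table2", seed: int = 0, outdir: str | None = None,
    model: str = "plsda",
) -> pd.DataFrame:
    """Run every tissue scheme (or the paired-subgroup layout) on a default
    synthetic cohort and emit the correspondingly shaped metrics table.

    The numbers differ from the clinical report — the original spectra are not
    public — but the table shape, protocol and metric arithmetic are the same.
    """
    if layout == "table2":
        schemes = (
            "berden_focal_vs_mixed", "normal_glomeruli_N0_vs_N1N2", "ifta_T0_vs_T1",
            "necrotising", "infiltrate", "arteritis", "vessel_necrosis",
        )
        frames = []
        for scheme in schemes:
            cfg = ExperimentConfig(
                scheme=scheme, model=model, simulate={"specimen": "tissue"}, seed=seed
            )
            frames.append(run_experiment(cfg).summary())
        df = pd.concat(frames, ignore_index=True)
    elif layout == "table3":
        cfg_t = ExperimentConfig(
            scheme="ifta_T0_vs_T1", model=model, simulate={"specimen": "tissue"}, seed=seed
        )
        cfg_u = ExperimentConfig(
            scheme="ifta_T0_vs_T1", model=model, simulate={"specimen": "urine"}, seed=seed
        )
        df = run_paired_comparison(cfg_t, cfg_u)
    else:
        raise ValueError("layout must be 'table2' or 'table3'")
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(outdir) / f"reproduce_{layout}.csv", index=False)
    return df
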