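import numpy as np
import pytest

from specdiscrim.cohort import CohortSpec, generate_tissue_cohort
from specdiscrim.data import build_class_labels, mean_spectrum
from specdiscrim.preprocess import PreprocessConfig, preprocess


@pytest.fixture(scope="session")
def tissue_cohort():
    """Default synthetic tissue cohort (27 samples x 3 replicates), seed 0."""
    return generate_tissue_cohort(CohortSpec.tissue_default(seed=0))


@pytest.fixture(scope="session")
def necrotising_preprocessed(tissue_cohort):
    """Preprocessed replicate and mean spectra labelled for the necrotising
    scheme; returns (train_set, test_set, labelled_total, means, truth)."""
    sset, meta, truth = tissue_cohort
    total = sset.with_labels(build_class_labels(meta, "necrotising"))
    means = mean_spectrum(total)
    tr, te, _ = preprocess(PreprocessConfig(), total, means)
    return tr, te, total, means, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
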