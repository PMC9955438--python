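import numpy as np
import pytest

import sersdx
from sersdx import CohortConfig, SpectrumSet, preprocess_pipeline, generate_cohort

CLASS_ORDER = [sersdx.HEALTHY, sersdx.STONE, sersdx.POLYP]


@pytest.fixture(scope="session")
def class_order():
    return list(CLASS_ORDER)


@pytest.fixture(scope="session")
def default_cohort():
    """The default 148-sample synthetic cohort (seed 0), raw spectra."""
    sset, truth = generate_cohort(CohortConfig(seed=0))
    return sset, truth


@pytest.fixture(scope="session")
def preprocessed_cohort(default_cohort):
    """Default cohort after the full smoothing/baseline/normalization chain."""
    sset, _ = default_cohort
    return preprocess_pipeline(sset)


@pytest.fixture(scope="session")
def separable_blobs():
    """Small, strongly separated 2-class matrix for classifier sanity checks."""
    rng = np.random.default_rng(42)
    n, p = 30, 12
    a = rng.normal(0.0, 0.3, size=(n, p))
    b = rng.normal(0.0, 0.3, size=(n, p))
    b[:, :4] += 4.0
    X = np.vstack([a, b])
    labels = np.array(["neg"] * n + ["pos"] * n, dtype=object)
    return X, labels


def make_spectrumset(intensities, wavenumbers=None, labels=None, ids=None):
    intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
    n, p = intensities.shape
    return SpectrumSet(
        wavenumbers=np.arange(p, dtype=float) if wavenumbers is None else wavenumbers,
        intensities=intensities,
        labels=np.array(labels if labels is not None else ["x"] * n, dtype=object),
        sample_ids=np.array(
            ids if ids is not None else [f"s{i}" for i in range(n)], dtype=object
        ),
    )
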