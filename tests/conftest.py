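"""Shared fixtures.

The expensive fixtures (full 3-hour datasets with extracted feature
matrices) are session-scoped so the imbalance and separability checks reuse
one extraction pass.
"""

from __future__ import annotations

import numpy as np
import pytest

import aeegrf as a


@pytest.fixture(scope="session")
def features_100_35():
    """Feature matrix of the default synthetic study: 100 normal / 35 abnormal,
    3-hour recordings at 1 Hz."""
    recs = a.make_dataset(100, 35, a.SynthesisConfig(seed=11))
    X, names, labels = a.extract_matrix(recs)
    return X, names, labels


@pytest.fixture(scope="session")
def features_150_30():
    """Imbalanced fixture (150 normal / 30 abnormal) for class-weight checks."""
    recs = a.make_dataset(150, 30, a.SynthesisConfig(seed=12))
    X, names, labels = a.extract_matrix(recs)
    return X, names, labels


@pytest.fixture(scope="session")
def small_features():
    """Cheap feature matrix from 30-minute recordings, for fast forest tests."""
    recs = a.make_dataset(24, 10, a.SynthesisConfig(duration_s=1800.0, seed=5))
    X, names, labels = a.extract_matrix(recs)
    return X, names, labels


@pytest.fixture
def rng():
    return np.random.default_rng(0)
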