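"""Shared fixtures: small corpora are generated programmatically per session."""

from __future__ import annotations

import numpy as np
import pytest

from cognitrace.corpus import CLASSES, split_patients
from cognitrace.fusion_model import precompute_features
from cognitrace.synthetic_data import generate_corpus


@pytest.fixture(scope="session")
def tiny_corpus():
    """5 patients per class; fast substrate for unit tests."""
    return generate_corpus({c: 5 for c in CLASSES}, seed=101)


@pytest.fixture(scope="session")
def small_corpus():
    """20 patients per class with a precomputed feature cache."""
    records = generate_corpus({c: 20 for c in CLASSES}, seed=202)
    cache = precompute_features(records)
    return records, cache


@pytest.fixture(scope="session")
def study_corpus():
    """The balanced 300-patient corpus used by the stress-test criteria."""
    records = generate_corpus({c: 100 for c in CLASSES}, seed=5)
    cache = precompute_features(records)
    assignment = split_patients(records, seed=1)
    return records, cache, assignment


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
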