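import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cwqspr.splits import SplitAssignment, make_splits
from cwqspr.synth import SyntheticSpec, generate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """400 molecules, mild noise — quick end-to-end material."""
    return generate(SyntheticSpec(n_molecules=400, noise_sigma=0.2, seed=42))


@pytest.fixture(scope="session")
def small_splits(small_dataset):
    return make_splits(small_dataset.frame["id"].tolist(), 3, seed=7)


@pytest.fixture
def tiny_split():
    """Hand-built 12-record split: A/P get 4, C/V get 2 each."""
    ids = [f"mol{i+1}" for i in range(12)]
    labels = ["A"] * 4 + ["P"] * 4 + ["C"] * 2 + ["V"] * 2
    return SplitAssignment(1, dict(zip(ids, labels)))
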