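import numpy as np
import pandas as pd
import pytest

from omicstack import OmicsDataset, SampleMetadata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(rng, n_features=10, n_samples=6, name="omic", prefix="f", center=False):
    x = rng.standard_normal((n_features, n_samples))
    if center:
        x = x - x.mean(axis=1, keepdims=True)
    return OmicsDataset(
        name,
        tuple(f"{prefix}{i+1}" for i in range(n_features)),
        tuple(f"s{j+1}" for j in range(n_samples)),
        x,
    )


@pytest.fixture
def small_dataset(rng):
    return make_dataset(rng)


@pytest.fixture
def two_group_metadata():
    frame = pd.DataFrame(
        {"group": ["g1", "g1", "g1", "g2", "g2", "g2"], "age": [50.0, 61.0, 55.0, 47.0, 66.0, 58.0]},
        index=[f"s{j+1}" for j in range(6)],
    )
    return SampleMetadata(frame, categorical=["group"], numeric=["age"])
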