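import numpy as np
import pandas as pd
import pytest

from allomorph.io import LandmarkDataset, LandmarkScheme


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_scheme():
    """4 points, two bones, one semilandmark."""
    labels = ("a", "b", "c", "d")
    return LandmarkScheme(
        point_labels=labels,
        bone_of={"a": "jaw", "b": "jaw", "c": "jaw", "d": "cranium"},
        is_semilandmark={"a": False, "b": False, "c": False, "d": True},
    )


@pytest.fixture
def toy_dataset(toy_scheme, rng):
    coords = rng.normal(size=(3, 4, 3))
    meta = pd.DataFrame({"specimen": ["s1", "s2", "s3"]})
    return LandmarkDataset(coords, toy_scheme, meta)


def random_configuration(rng, k=6):
    x = rng.normal(size=(k, 3))
    return x - x.mean(axis=0)
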