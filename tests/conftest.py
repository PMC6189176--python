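import numpy as np
import pytest

from substage import (
    BiomarkerDataset,
    NoiseModel,
    SubtypeSequence,
    ZScoreEventSet,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def single_biomarker_events():
    """One biomarker with events z=1, z=2 and cap 3 (N=2)."""
    return ZScoreEventSet(["bm0"], [np.array([1.0, 2.0])], np.array([3.0]))


@pytest.fixture
def three_flat_events():
    """Three biomarkers with a single z=1 event each (N=3, no ordering ties)."""
    return ZScoreEventSet.uniform(["a", "b", "c"], z=(1.0,), z_max=2.0)


@pytest.fixture
def five_flat_events():
    """Five biomarkers with a single z=1 event each (N=5, 120 sequences)."""
    return ZScoreEventSet.uniform(list("abcde"), z=(1.0,), z_max=2.0)


def make_dataset(values, names=None):
    values = np.atleast_2d(np.asarray(values, float))
    names = names or [f"bm{i}" for i in range(values.shape[1])]
    return BiomarkerDataset(values, names)


@pytest.fixture
def unit_noise():
    return lambda n: NoiseModel.unit(n)


def sequential_sequence(n):
    return SubtypeSequence(np.arange(n))
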