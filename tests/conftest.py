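import numpy as np
import pytest

from stonect import LaplacianKernel, StoneLabel, TrainingSet
from stonect.classify import classify_cutoff


@pytest.fixture(params=["inverse_distance", "uniform"])
def kernel(request) -> LaplacianKernel:
    return LaplacianKernel(scheme=request.param)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230917)


@pytest.fixture
def cutoff_labeled_train(rng) -> TrainingSet:
    """200 random feature points labelled by the rigid-cutoff rule.

    A deterministic surrogate training set whose decision structure is known
    exactly, so kNN behaviour can be checked against the cutoff geometry.
    """
    max_hu = rng.uniform(100, 1900, size=200)
    pp_lapl = rng.uniform(0, 550, size=200)
    labels = [classify_cutoff((m, p)) for m, p in zip(max_hu, pp_lapl)]
    return TrainingSet(max_hu=max_hu, pp_lapl=pp_lapl, labels=labels, provenance="surrogate")
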