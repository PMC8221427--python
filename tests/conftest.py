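import numpy as np
import pytest

from tasselkit import classifier as clf
from tasselkit.synthetic import FieldConfig, generate_field, generate_patch_dataset


@pytest.fixture(scope="session")
def patch_dataset():
    """Default synthetic patch dataset: 200 per class, seed 0."""
    return generate_patch_dataset(200, seed=0)


@pytest.fixture(scope="session")
def reference_model(patch_dataset):
    return clf.train(patch_dataset, seed=0)


@pytest.fixture(scope="session")
def field_seed0():
    """Seed-0 fast-test scene (1000x1000, 15 tassels) plus ground truth."""
    return generate_field(FieldConfig.test_scale(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_always_model(always_positive: bool) -> clf.ClassifierModel:
    """A degenerate classifier that votes one way on every patch."""
    return clf.ClassifierModel(
        coef=np.zeros(clf.N_FEATURES),
        intercept=50.0 if always_positive else -50.0,
        feature_mean=np.zeros(clf.N_FEATURES),
        feature_scale=np.ones(clf.N_FEATURES),
    )
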