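import numpy as np
import pytest

from deepdismisl.bag_data import InstanceFeatureBag, SurvivalRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tiny_cohort(n_bags=12, bag_size=24, feature_dim=4, seed=7):
    """Small hand-rolled cohort with a crude signal in feature column 0."""
    rng = np.random.default_rng(seed)
    cohort = []
    for b in range(n_bags):
        level = rng.normal()
        X = rng.normal(size=(bag_size, feature_dim))
        X[:, 0] += level
        t = float(rng.exponential(np.exp(-level) * 10) + 0.1)
        e = int(rng.random() < 0.7)
        cohort.append(
            (
                InstanceFeatureBag(f"b{b:02d}", X),
                SurvivalRecord(f"b{b:02d}", t, e),
            )
        )
    return cohort


@pytest.fixture
def tiny_cohort():
    return make_tiny_cohort()
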