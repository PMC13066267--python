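import numpy as np
import pytest

from cohortssm.population import PopulationModel, SubjectFeatureSet
from cohortssm.ssm import SSMConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return SSMConfig(model_dim=8, expansion=2, state_dim=4)


@pytest.fixture
def small_model(small_config):
    return PopulationModel.init(small_config, seed=3)


@pytest.fixture
def small_set(rng):
    n, d = 10, 8
    return SubjectFeatureSet(
        features=rng.standard_normal((n, d)).astype(np.float32),
        subject_ids=np.array([f"s{i}" for i in range(n)]),
        labels=rng.integers(0, 2, n))
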