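import numpy as np
import pytest

from tiltnirs import GroundTruth, build_session


@pytest.fixture(scope="session")
def default_design():
    return build_session(0, rng_seed=1)


@pytest.fixture()
def noise_free_truth():
    return GroundTruth().zero_noise()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
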