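import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg():
    """Short-scan cohort config shared by fast tests."""
    from sleepfc import SyntheticCohortConfig
    return SyntheticCohortConfig(seed=42, n_volumes=600, n_control=2,
                                 n_lesion=2)


@pytest.fixture(scope="session")
def default_cfg():
    from sleepfc import SyntheticCohortConfig
    return SyntheticCohortConfig(seed=7)


@pytest.fixture(scope="session")
def one_subject(default_cfg):
    from sleepfc import generate_subject
    return generate_subject(default_cfg, "control", subject_seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
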