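import numpy as np
import pytest

from eogdeco.protocol import build_default_protocol
from eogdeco.synthetic_eog import UserProfile


@pytest.fixture(scope="session")
def default_protocol():
    return build_default_protocol(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def quiet_profile():
    """Noise-free, drift-free profile for deterministic signal checks."""
    return UserProfile(noise_std=0.0, drift_rate=0.0, gain_jitter_std=0.0, seed=7)


@pytest.fixture()
def small_profile():
    """Small, moderately noisy profile for fast pipeline tests."""
    return UserProfile(
        amplitude_scale=600.0,
        motion_duration_mean=0.3,
        motion_duration_std=0.05,
        noise_std=20.0,
        drift_rate=5.0,
        seed=11,
    )
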