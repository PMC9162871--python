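import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from texstack import RoiMask, SynthParams, Volume

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A small, fully usable synthetic cohort."""
    return SynthParams(
        n_initial=16, n_missing_sequences=0, n_missing_egfr=0, prevalence=0.5, seed=7
    )


@pytest.fixture
def random_volume(rng):
    data = rng.normal(size=(6, 8, 8))
    return Volume(data, (2.0, 1.0, 1.0))


@pytest.fixture
def ball_mask():
    """Digital ball of radius 10 voxels at unit spacing."""
    r = 10
    z, y, x = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return RoiMask(z**2 + y**2 + x**2 <= r**2, (1.0, 1.0, 1.0))
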