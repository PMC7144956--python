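import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from imatq import AM, BFL, VL, PhantomSpec, make_phantom

settings.register_profile(
    "deterministic", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, bias-free, zero-partial-volume subject with known truth."""
    spec = PhantomSpec(noise_sd=0.0, bias_amplitude=0.0,
                       partial_volume_width=0.0,
                       fat_fractions={VL: 0.25, AM: 0.15, BFL: 0.40},
                       rng_seed=11)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default study conditions: noise, bias field and partial volume on."""
    spec = PhantomSpec(rng_seed=7)
    return make_phantom(spec)
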