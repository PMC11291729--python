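import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import patchkit as pk

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    max_examples=50,
)
settings.load_profile("default")


@pytest.fixture
def symmetric_model():
    """Two-state C<->O chain with equal rates (stationary Popen = 0.5)."""
    return pk.two_state_model(opening_rate=100.0, closing_rate=100.0)


@pytest.fixture
def quiet_acq():
    """Noiseless, unfiltered acquisition: exact rendering."""
    return pk.AcquisitionSpec(noise_sd_pa=0.0, filter_cutoff_hz=None)


@pytest.fixture
def default_acq():
    return pk.AcquisitionSpec()


def random_idealized(rng: np.random.Generator, max_level: int = 2,
                     n_dwells: int = 40) -> pk.IdealizedTrace:
    """Random level/duration sequence for property tests."""
    levels = rng.integers(0, max_level + 1, size=n_dwells)
    durations = rng.exponential(0.05, size=n_dwells) + 1e-4
    return pk.IdealizedTrace(levels=levels, durations=durations)
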