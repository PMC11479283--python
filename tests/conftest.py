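import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spectraleaf as sl

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_data() -> sl.LeafDataset:
    """One full-size dataset under the study conditions (n=200, 5 nm grid)."""
    return sl.generate_dataset(sl.default_config(), seed=1)


@pytest.fixture(scope="session")
def small_data() -> sl.LeafDataset:
    """A coarse, fast dataset for structural/IO tests."""
    cfg = sl.GeneratorConfig(n_samples=24, wavelength_step=100.0, n_time_points=15)
    return sl.generate_dataset(cfg, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
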