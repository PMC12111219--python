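import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hydrolens.materials import load_registry
from hydrolens.synthetic import contaflex_preset, gen_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def noiseless_cohort():
    return gen_cohort(contaflex_preset(noiseless=True))


@pytest.fixture(scope="session")
def noisy_cohort():
    return gen_cohort(contaflex_preset(seed=1))


@pytest.fixture()
def small_cohort():
    """Coarse cohort for I/O round-trip tests: small files, fast."""
    cfg = contaflex_preset(seed=7)
    cfg = dataclasses.replace(
        cfg,
        times=np.arange(0.0, 24.0 + 1e-9, 0.5),
        samples_per_group=2,
        lidar_samples=1,
        lidar_duration_h=14.0,
        lidar_fs_hz=0.05,
    )
    return gen_cohort(cfg)
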