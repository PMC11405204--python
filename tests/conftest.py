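import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# the generator logs a warning per clipped probability; keep test output sane
logging.getLogger("seiznet").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_well():
    from seiznet.synth import WellConfig

    return WellConfig(
        n_electrodes=8, duration=60.0, base_rate=2.0, burst_rate=0.0, seed=7
    )
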