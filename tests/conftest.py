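import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Seed-dropping and SD-with-one-experiment warnings are part of normal
    operation on synthetic fields; tests assert on them explicitly where
    they matter."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="dropped .* seed", category=UserWarning)
        yield
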