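import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

import tfbsevol as tv


@pytest.fixture(scope="session")
def baseline():
    """The canonical parameter point: n=7, eps=2 k_BT, mu=4 k_BT."""
    return tv.BindingModel(n=7, epsilon=2.0, mu=4.0)


@pytest.fixture(scope="session")
def baseline_classes(baseline):
    return tv.classify_binding(baseline)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
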