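import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def grid53():
    """The 5 x 3 grid used throughout the dose-optimization scenarios."""
    from locrm import DoseGrid
    return DoseGrid(rawA=(0.08, 0.16, 0.24, 0.32, 0.40), rawB=(0.08, 0.16, 0.24))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
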