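import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from perilesion.model import SegmentedModelParams

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


#: The published segmented-model point estimates used as worked-example
#: inputs and as simulation truth throughout the suite.
PUBLISHED = SegmentedModelParams(
    beta0=9.0, beta_t=-0.07, b1=-1.53, b2=-0.46, b3=0.56, knot=2.05,
    sigma_u=2.0, sigma_e=3.0,
)

#: Published 95% CI bands for the recovery plausibility checks.
KNOT_CI = (1.26, 2.84)
AFTER_KNOT_CI = (0.42, 0.70)
TIME_CI = (-0.08, -0.06)


@pytest.fixture
def published_params():
    return PUBLISHED


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
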