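import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# The 11-point worked-example series whose k = 5 similarity graph has
# 13 edges, 3 components, 2 bridges, 3 missing direct edges, 1 isolated
# node and 6 triangles.
FIG1_SERIES = np.array([9, 10, 10, 8, 7, 8, 7, 6, 5, 10, 9], dtype=float)


@pytest.fixture
def fig1_series():
    return FIG1_SERIES.copy()


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
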