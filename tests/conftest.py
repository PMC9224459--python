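import matplotlib
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

matplotlib.use("Agg")

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def time_grid():
    """Default experimental sampling design: t=0 plus 2-240 min."""
    return np.concatenate([[0.0], np.geomspace(2.0, 240.0, 12)])


@pytest.fixture
def reference_params():
    """One well-separated parameter set per model, for recovery checks."""
    return {
        "first_order": {"k": 0.02},
        "weibull": {"b": 9.37e-5, "n": 2.981},
        "distinct_isoenzymes": {"A_L": 0.6, "A_S": 0.4, "k_L": 0.06, "k_R": 0.006},
        "two_fraction": {"a": 0.7, "k_L": 0.08, "k_R": 0.008},
        "multicomponent": {"k_1": 0.08, "k_2": 0.008, "r": 0.5},
        "series_type": {"alpha_1": 0.4, "k_1": 0.05, "k_2": 0.005},
        "nth_order": {"k": 0.01, "n": 1.5},
        "fractional_conversion": {"A_r": 0.2, "k": 0.03},
    }
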