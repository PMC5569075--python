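import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def default_bounds():
    from scission import transparency_bounds

    return transparency_bounds(84.0, 169.0)


@pytest.fixture
def three_subject_proportions():
    """Hand-checkable per-subject completion proportions, one condition."""
    return pd.DataFrame(
        {
            "subject_id": ["a", "a", "b", "b", "c", "c"],
            "experiment": "exp1",
            "condition": "L55",
            "color_scheme": "red_green",
            "center_luminance_cdm2": 54.9,
            "coded_level": 6,
            "response": [
                "completion", "no_completion",   # a: 0.5
                "completion", "completion",      # b: 1.0
                "no_completion", "no_afterimage",  # c: 0.0
            ],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20170823)
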