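import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def two_pop_truth():
    """Minimal single-condition ground truth: alpha_P=2, alpha_Q=5."""
    return pd.DataFrame(
        [
            {"cell_line": "cl1", "stimulus": "st1", "population": "P", "ion": "ionA", "alpha": 2.0},
            {"cell_line": "cl1", "stimulus": "st1", "population": "Q", "ion": "ionA", "alpha": 5.0},
        ]
    )


@pytest.fixture
def random_truth():
    from mixdeconv.simulate import make_truth

    return make_truth(20, seed=123)


@pytest.fixture
def planted_events():
    from mixdeconv.simulate import simulate_cytometry_events

    fractions = {"G0": 0.4, "G1": 0.3, "S": 0.2, "G2M": 0.1}
    events = simulate_cytometry_events(10_000, fractions, seed=7)
    return events, fractions


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
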