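import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_panel(values: dict) -> pd.DataFrame:
    """Build a tidy panel from {(cultivar, indicator): (control, stress)}
    replicate tuples."""
    rows = []
    for (cultivar, indicator), (control, stress) in values.items():
        for cond, reps in (("control", control), ("stress", stress)):
            for r, v in enumerate(reps, start=1):
                rows.append(
                    {
                        "cultivar": cultivar,
                        "indicator": indicator,
                        "condition": cond,
                        "replicate": r,
                        "value": float(v),
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def two_indicator_panel():
    """Two cultivars x two indicators, exact hand-checkable values."""
    return make_panel(
        {
            ("a", "SOD"): ((10, 10, 10), (15, 15, 15)),
            ("a", "MDA"): ((8, 10, 12), (5, 5, 5)),
            ("b", "SOD"): ((10, 10, 10), (10, 10, 10)),
            ("b", "MDA"): ((10, 10, 10), (20, 20, 20)),
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240924)
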