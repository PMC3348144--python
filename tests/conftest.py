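import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_survey():
    """Four 1-ha plots, two genera, one duplicate (plot, genus) record."""
    return pd.DataFrame(
        {
            "plot_id": [0, 0, 1, 1, 2, 3],
            "x_km": [0.0, 0.0, 10.0, 10.0, 0.0, 10.0],
            "y_km": [0.0, 0.0, 0.0, 0.0, 10.0, 10.0],
            "genus": ["Hymenaea", "Hymenaea", "Hymenaea", "Swartzia", "Swartzia", "Goupia"],
            "volume_m3": [4.0, 6.0, 2.0, 5.0, 3.0, 1.0],
        }
    )


@pytest.fixture
def small_prices():
    return pd.DataFrame(
        {
            "genus": ["Hymenaea", "Swartzia", "Goupia"],
            "price_usd_per_m3": [569.0, 105.0, 257.0],
            "years": ["2006-2007"] * 3,
        }
    )


@pytest.fixture
def scattered_points(rng):
    """80 points over a 100x100 km square."""
    return np.column_stack([rng.uniform(0, 100, 80), rng.uniform(0, 100, 80)])
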