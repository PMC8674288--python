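import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from moorbloom import synthetic

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ml_noiseless():
    """Default mixed-layer scenario, exact backbone (no noise)."""
    return synthetic.generate_scenario(regime="ML", seed=0, noise=False)


@pytest.fixture(scope="session")
def mw_noiseless():
    """Default meltwater scenario, exact backbone (no noise)."""
    return synthetic.generate_scenario(regime="MW", seed=0, noise=False)


@pytest.fixture(scope="session")
def ml_noisy():
    return synthetic.generate_scenario(regime="ML", seed=7, noise=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def hourly_index():
    return pd.date_range("2018-01-01", periods=1200, freq="h")
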