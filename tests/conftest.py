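import numpy as np
import pandas as pd
import pytest

from ecocorr import CountryPanel, SimulationConfig, VariableMeta, generate_panel


@pytest.fixture
def tiny_panel():
    """3 countries x 3 variables with one missing cell."""
    values = pd.DataFrame(
        {"wheat": [100.0, 120.0, 90.0],
         "milk": [200.0, np.nan, 150.0],
         "cancer01_male": [30.0, 45.0, 25.0]},
        index=pd.Index(["Alandia", "Borland", "Cestia"], name="country"))
    return CountryPanel(values)


@pytest.fixture(scope="session")
def default_panel():
    """One synthetic panel at the reference conditions (39 x 68 + extras)."""
    panel, truth = generate_panel(SimulationConfig(seed=7))
    return panel, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
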