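import numpy as np
import pandas as pd
import pytest

from bushmarket import synthetic_market as sm
from bushmarket.cli import _demo_scenario_path


@pytest.fixture(scope="session")
def study_scenario() -> sm.ScenarioConfig:
    """Packaged demo scenario: the study-shaped market (156 months from
    1997-10, three periods, four sqrt-scale shocks on the primate group)."""
    return sm.scenario_from_yaml(_demo_scenario_path())


@pytest.fixture(scope="session")
def study_noise(study_scenario):
    """The fitted noise model used as simulation truth: ARIMA(2,0,0)x(1,0,0)_12
    with ar = (0.343, 0.301), seasonal ar = 0.208."""
    return study_scenario.noise


@pytest.fixture(scope="session")
def study_events(study_scenario):
    """The four external shocks with their published transfer weights."""
    return study_scenario.interventions


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def study_months() -> pd.PeriodIndex:
    return pd.period_range("1997-10", periods=156, freq="M")
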