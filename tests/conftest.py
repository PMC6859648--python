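import numpy as np
import pandas as pd
import pytest

from aqfuse.meteorology import MetHour, Stability
from aqfuse.pipeline import run_scenario
from aqfuse.synthetic import ScenarioConfig, generate_scenario


@pytest.fixture
def neutral_met() -> MetHour:
    """Westerly 3 m/s, neutral, 800 m mixing height."""
    return MetHour(
        timestamp=pd.Timestamp("2020-01-01 12:00"),
        wind_speed=3.0, wind_direction=270.0, monin_obukhov_L=1.0e6,
        mixing_height=800.0, stability=Stability.NEUTRAL, season="winter",
    )


def small_config(seed: int, **overrides) -> ScenarioConfig:
    """Reduced problem size used throughout the suite: 500-m receptor
    grid, one month of met, 20 representative hours, coarse quadrature."""
    kw = dict(
        seed=seed, spacing_m=500.0, met_hours=720, n_representative=20,
        line_alongwind=25.0, area_refinement=0.2,
    )
    kw.update(overrides)
    return ScenarioConfig(**kw)


@pytest.fixture(scope="session")
def small_scenario():
    """One shared reduced scenario for tests that only read from it."""
    return generate_scenario(small_config(101))


@pytest.fixture(scope="session")
def small_pipeline():
    """One shared end-to-end pipeline run on a reduced scenario."""
    return run_scenario(
        small_config(202), fuse_grid=True,
        stationary_hours=720, n_campaign_days=20,
    )
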