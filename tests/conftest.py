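import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from erposcm.simulate import EffectProfile, FactorModelConfig, generate_panel

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_null_study():
    """One treated + 8 donors, no injected effect, moderate noise."""
    cfg = FactorModelConfig(
        n_treated=1, n_donors=8, seed=11, pop_log_mean=float(np.log(8e6)), pop_log_sd=0.3
    )
    return generate_panel(cfg)


@pytest.fixture(scope="session")
def step_effect_study():
    """One treated + 10 donors with a -20% step effect from 2018-01."""
    cfg = FactorModelConfig(
        n_treated=1, n_donors=10, seed=21, pop_log_mean=float(np.log(8e6)), pop_log_sd=0.3
    )
    return generate_panel(cfg, EffectProfile(shape="step", delta=-0.2, start="2018-01-01"))


@pytest.fixture()
def toy_populations():
    states = ["A", "B", "C"]
    years = range(2014, 2022)
    return pd.DataFrame(
        [(s, y, 6_500_000) for s in states for y in years],
        columns=["state", "year", "population"],
    )
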