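import numpy as np
import pytest

import previnc as pv
from previnc.illness_death import _steady_prevalence

GAP = 8


@pytest.fixture(scope="session")
def stationary_curves():
    """Two surveys of the same stationary world with constant incidence 0.001."""
    p = pv.closed_form_constant_rates(np.full(20, 1e-3), np.arange(20, dtype=float))
    return (
        pv.PrevalenceCurve(p, year=2001),
        pv.PrevalenceCurve(p, year=2009),
    )


@pytest.fixture(scope="session")
def unimodal_scenario():
    """Unit-multiplier unimodal scenario: peak 30 per 100k at age 10."""
    return pv.ScenarioConfig(
        family="type1-like",
        peak_rate=30.0,
        sex_scale={"female": 1.0, "male": 1.0},
        race_scale={"NHW": 1.0, "NHB": 1.0, "Hispanic": 1.0, "Other": 1.0},
    )


@pytest.fixture(scope="session")
def unimodal_noise_free(unimodal_scenario):
    """Noise-free stationary prevalence curves under the unimodal truth."""
    p = _steady_prevalence(unimodal_scenario, "male", "NHW")
    truth = pv.incidence_grid(unimodal_scenario, "male", "NHW")
    return pv.PrevalenceCurve(p, 2001), pv.PrevalenceCurve(p, 2009), truth


@pytest.fixture(scope="session")
def small_world():
    """One realized synthetic world at survey-like denominators."""
    return pv.generate_world(pv.default_scenario("type1-like"), seed=20010)
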