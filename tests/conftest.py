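import logging

import numpy as np
import pytest

from lbpseudo import LBRCSample, calibrate_censoring, scenario_model

logging.getLogger("lbpseudo").setLevel(logging.ERROR)


@pytest.fixture
def toy_sample() -> LBRCSample:
    """Three-subject worked example: two events (0.6, 1.0), one censored.

    Hand-evaluated curves: Wang product-limit = 1, 1/2, 0 on the three
    segments; left-truncated KM = 1, 2/3, 0; the NPMLE places masses
    (1/3, 2/3) on the two event times.
    """
    return LBRCSample(
        a=[0.2, 0.5, 0.1],
        y=[1.0, 0.8, 0.6],
        delta=[1, 0, 1],
        x=np.zeros((3, 1)),
    )


@pytest.fixture(scope="session")
def scenario1():
    return scenario_model("I")


@pytest.fixture(scope="session")
def scenario1_null():
    """Constant baseline with no covariate effects (closed-form S = e^{-2t})."""
    return scenario_model("I", beta=(0.0, 0.0))


@pytest.fixture(scope="session")
def censor_scale_cache():
    """Censoring scales calibrated once per (scenario, rate) for the session."""
    cache = {}

    def get(scenario: str, rate: float, beta=None) -> float:
        key = (scenario, rate, beta)
        if key not in cache:
            model = scenario_model(scenario) if beta is None else scenario_model(scenario, beta=beta)
            cache[key] = calibrate_censoring(model, rate, seed=1)
        return cache[key]

    return get
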