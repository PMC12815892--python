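import numpy as np
import pytest

from rgsurv import ScenarioConfig, generate_cohort, induce_error
from rgsurv.simulation import validation_from


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def make_validation(scenario: str, m: int, seed: int, mechanism: str = "exponential"):
    """Simulated validation sample (gold + error-prone pairs) for one scenario."""
    from rgsurv.simulation import SCENARIOS
    theta, lfp, ld = SCENARIOS[scenario]
    cfg = ScenarioConfig.scenario(scenario, m=m)
    gen = np.random.default_rng(seed)
    cohort = generate_cohort(m, cfg.alpha, cfg.rate_val, cfg.tau, cfg.censor_prob, gen)
    obs = induce_error(cohort, theta, lfp, ld, gen, cfg.tau, mechanism=mechanism)
    return cohort, obs, validation_from(cohort, obs)


@pytest.fixture
def perfect_validation():
    """Validation data with no measurement error (gold == error-prone)."""
    _, _, val = make_validation("A", m=400, seed=5)
    return val
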