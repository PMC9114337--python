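import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from metacontrol import (
    ModelParams,
    generate_trial_plan,
    simulate_agent,
    study1_layout,
    study2_layout,
)


@pytest.fixture(scope="session")
def s2_layout():
    return study2_layout()


@pytest.fixture(scope="session")
def s1_layout():
    return study1_layout()


@pytest.fixture(scope="session")
def s2_plan(s2_layout):
    return generate_trial_plan(s2_layout, counterbalance_id=0, seed=11)


@pytest.fixture(scope="session")
def s1_plan(s1_layout):
    return generate_trial_plan(s1_layout, counterbalance_id=1, seed=11)


@pytest.fixture(scope="session")
def s2_params():
    return ModelParams(
        alpha=0.45, beta=1.1, omega={"low": 0.25, "high": 0.65}, pi=0.15, rho=-0.1
    )


@pytest.fixture(scope="session")
def s1_params():
    return ModelParams(
        alpha=0.4, beta=0.9, lam=0.55, eta=0.6, eta_cf=0.4, pi=0.1, rho=0.2,
        omega={
            "stable_low": 0.2, "stable_high": 0.6,
            "variable_low": 0.15, "variable_high": 0.45,
        },
    )


@pytest.fixture(scope="session")
def s2_behavior(s2_params, s2_plan):
    return simulate_agent(s2_params, s2_plan, seed=21)


@pytest.fixture(scope="session")
def s1_behavior(s1_params, s1_plan):
    return simulate_agent(s1_params, s1_plan, seed=22, missing_rate=0.03)
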