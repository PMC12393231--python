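import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from telic import (  # noqa: E402
    CapacityBound,
    ComplexityConfig,
    EnvironmentSpec,
    GoalSpec,
    PolicyDomain,
    PolicyParams,
    Region,
    TelicRule,
    generate_fixture,
)


@pytest.fixture(scope="session")
def env():
    return EnvironmentSpec(horizon=30, start=0.0)


@pytest.fixture(scope="session")
def dual_goal():
    return GoalSpec(
        regions={"R": Region(center=2.0), "L": Region(center=-2.0)}, target="R"
    )


@pytest.fixture(scope="session")
def shifted_goal():
    return GoalSpec(
        regions={"R": Region(center=2.5), "L": Region(center=-2.0)}, target="R"
    )


@pytest.fixture(scope="session")
def rule():
    return TelicRule(epsilon=0.1)


@pytest.fixture(scope="session")
def cfg():
    return ComplexityConfig()


@pytest.fixture(scope="session")
def domain():
    return PolicyDomain()


@pytest.fixture(scope="session")
def coarse_domain():
    # same extent as the default grid at desk-check resolution
    return PolicyDomain(n_mu=61, n_sigma=31)


@pytest.fixture(scope="session")
def tiny_domain():
    return generate_fixture("tiny_grid").domain


@pytest.fixture(scope="session")
def pi0():
    return PolicyParams(mu=0.0, sigma=1.0)


@pytest.fixture(scope="session")
def dual_rep(dual_goal, rule, env, domain):
    from telic import build_representation

    return build_representation(dual_goal, rule, env, domain)


@pytest.fixture(scope="session")
def shifted_rep(shifted_goal, rule, env, domain):
    from telic import build_representation

    return build_representation(shifted_goal, rule, env, domain)
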