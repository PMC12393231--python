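"""Policy complexity, information projections, reachability."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from telic import (
    CapacityBound,
    ComplexityConfig,
    EmptyStateError,
    EnvironmentSpec,
    PolicyParams,
    TelicRule,
    build_representation,
    information_projection,
    is_reachable,
    mc_policy_complexity,
    nearest_feasible_policy,
    policy_complexity,
)

LOG2 = math.log(2)

policies = st.builds(
    PolicyParams,
    mu=st.floats(-3, 3, allow_nan=False),
    sigma=st.floats(0.2, 3, allow_nan=False),
)


def test_self_divergence_is_zero(env):
    cfg = ComplexityConfig()
    assert policy_complexity(cfg.default_policy, cfg, env) == 0.0


@pytest.mark.parametrize(
    "policy, nats",
    [
        (PolicyParams(mu=0, sigma=2), math.log(0.5) + 2.0 - 0.5),  # 0.80685
        (PolicyParams(mu=1, sigma=1), 0.5),  # (d mu)^2 / 2 for equal sd
    ],
)
def test_closed_form_gaussian_kl(policy, nats, env):
    cfg_bits = ComplexityConfig(base="bits")
    cfg_nats = ComplexityConfig(base="nats")
    assert policy_complexity(policy, cfg_nats, env) == pytest.approx(nats, rel=1e-12)
    assert policy_complexity(policy, cfg_bits, env) == pytest.approx(
        nats / LOG2, rel=1e-12
    )


@given(policies)
def test_complexity_nonnegative_and_identity(env, p):
    cfg = ComplexityConfig()
    c = policy_complexity(p, cfg, env)
    assert c >= 0.0
    if (p.mu, p.sigma) != (0.0, 1.0):
        assert c > 0.0


@pytest.mark.parametrize("convention", ["endpoint", "per_step"])
@pytest.mark.parametrize("direction", ["forward", "reverse"])
def test_trajectory_level_is_horizon_times_step_level(convention, direction):
    env = EnvironmentSpec(horizon=30, param_convention=convention)
    env1 = EnvironmentSpec(horizon=1, param_convention="per_step")
    p = PolicyParams(mu=0.8, sigma=1.4)
    cfg_traj = ComplexityConfig(level="trajectory", direction=direction, base="nats")
    # step law of the 30-step walk, evaluated as a single-step policy
    from telic import step_distribution

    sp = step_distribution(p, env)
    sq = step_distribution(cfg_traj.default_policy, env)
    cfg_step = ComplexityConfig(
        default_policy=PolicyParams(mu=sq.mean, sigma=sq.sd),
        direction=direction,
        base="nats",
    )
    step_kl = policy_complexity(PolicyParams(mu=sp.mean, sigma=sp.sd), cfg_step, env1)
    assert policy_complexity(p, cfg_traj, env) == pytest.approx(30 * step_kl, rel=1e-12)


@pytest.mark.parametrize("level", ["endpoint", "trajectory"])
@pytest.mark.parametrize("direction", ["forward", "reverse"])
def test_mc_log_ratio_estimate_matches_closed_form(level, direction, env):
    cfg = ComplexityConfig(level=level, direction=direction, base="nats")
    p = PolicyParams(mu=0.9, sigma=1.3)
    est, se = mc_policy_complexity(p, cfg, env, n=100_000, seed=17)
    assert abs(est - policy_complexity(p, cfg, env)) < 3 * se


def test_projection_returns_default_when_state_contains_it(dual_goal, env, domain):
    # at eps small enough the R-state swallows every positive-score policy,
    # but pi0 scores exactly 0; project instead onto a state containing pi0
    rep = build_representation(dual_goal, TelicRule(epsilon=0.1), env, domain)
    cfg = ComplexityConfig(default_policy=PolicyParams(mu=1.0, sigma=1.0))
    proj = information_projection(rep.state("SR"), cfg, env, domain)
    assert proj.policy == cfg.default_policy
    assert proj.complexity == 0.0


def test_projection_is_grid_optimal_and_mirror_symmetric(dual_rep, cfg, env, domain):
    pr = information_projection(dual_rep.state("SR"), cfg, env, domain)
    pl = information_projection(dual_rep.state("SL"), cfg, env, domain)
    assert pr.complexity == pl.complexity
    assert pr.policy.mu == -pl.policy.mu and pr.policy.sigma == pl.policy.sigma
    # exhaustive optimality: no member beats the projection
    mu, sd = domain.meshgrid()
    from telic import policy_complexity_grid

    comp = policy_complexity_grid(mu, sd, cfg, env)
    assert comp[dual_rep.state("SR").member_mask].min() == pr.complexity


def test_projection_on_empty_state_raises(dual_goal, env, domain):
    rep = build_representation(dual_goal, TelicRule(epsilon=0.999), env, domain)
    with pytest.raises(EmptyStateError):
        information_projection(rep.state("SR"), ComplexityConfig(), env, domain)


def test_polished_projection_is_no_worse_than_grid(dual_rep, cfg, env, domain):
    grid = information_projection(dual_rep.state("SR"), cfg, env, domain)
    polished = information_projection(
        dual_rep.state("SR"), cfg, env, domain, polish=True, rep=dual_rep
    )
    assert polished.complexity <= grid.complexity


def test_reachability_witness_and_monotonicity_in_delta(
    dual_rep, shifted_rep, cfg, env, domain
):
    # dual-goal SR is reachable at delta=1: (1,1) is a member at 0.72135 bits
    r1 = is_reachable(dual_rep.state("SR"), cfg, CapacityBound(delta=1.0), env, domain)
    assert r1.reachable
    assert r1.witness.complexity <= 0.5 / LOG2
    assert policy_complexity(PolicyParams(mu=1, sigma=1), cfg, env) == pytest.approx(
        0.5 / LOG2
    )
    # shifted SR is not reachable at delta=0.25
    r2 = is_reachable(
        shifted_rep.state("SR"), cfg, CapacityBound(delta=0.25), env, domain
    )
    assert not r2.reachable
    # monotone: reachable at delta1 implies reachable at any delta2 >= delta1
    for d1, d2 in [(0.25, 1.0), (1.0, 5.0)]:
        a = is_reachable(dual_rep.state("SR"), cfg, CapacityBound(delta=d1), env, domain)
        b = is_reachable(dual_rep.state("SR"), cfg, CapacityBound(delta=d2), env, domain)
        if a.reachable:
            assert b.reachable


def test_nearest_feasible_policy_properties(shifted_rep, dual_rep, cfg, env, domain):
    bound = CapacityBound(delta=0.25)
    res = nearest_feasible_policy(shifted_rep.state("SR"), cfg, bound, env, domain)
    assert not res.feasible
    assert res.complexity <= bound.delta
    assert 0 < res.policy.mu < 2.5  # strictly between default and the region
    assert res.distance > 0
    # reachable state: returns the information projection itself
    res2 = nearest_feasible_policy(
        dual_rep.state("SR"), cfg, CapacityBound(delta=1.0), env, domain
    )
    proj = information_projection(dual_rep.state("SR"), cfg, env, domain)
    assert res2.policy == proj.policy and res2.distance == 0.0


def test_nearest_feasible_at_zero_capacity_evaluates_default(
    shifted_rep, cfg, env, domain
):
    res = nearest_feasible_policy(
        shifted_rep.state("SR"), cfg, CapacityBound(delta=0.0), env, domain
    )
    assert res.policy == cfg.default_policy
    assert res.complexity == 0.0
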