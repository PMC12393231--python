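"""Capacity-bounded controllability and refinement by state splitting."""

import pytest

from telic import (
    CapacityBound,
    ComplexityConfig,
    HopBudget,
    PolicyParams,
    SplitNotNeededError,
    TelicRule,
    build_representation,
    is_telic_controllable,
    refine_until_controllable,
    split_state,
)


def test_dual_goal_controllable_without_hops(dual_rep, cfg, env, domain):
    """Both SR and SL lie within one 1-bit leg of the default: (1, 1) is
    an SR member at 0.72135 bits, and SL mirrors it."""
    report = is_telic_controllable(
        dual_rep, cfg, CapacityBound(delta=1.0), HopBudget(n_hops=0), env, domain
    )
    assert report.controllable
    for lab in ("SR", "SL"):
        chain = report.per_state[lab].chain
        assert len(chain) == 1
        assert chain[0].complexity <= 1.0


def test_representation_anchored_inside_states_is_trivially_controllable(
    dual_goal, rule, env, domain
):
    """A default policy that is itself a member of a goal state reaches it
    at zero complexity for any capacity."""
    rep = build_representation(dual_goal, rule, env, domain)
    cfg = ComplexityConfig(default_policy=PolicyParams(mu=1.0, sigma=1.0))
    report = is_telic_controllable(
        rep, cfg, CapacityBound(delta=5.0), HopBudget(n_hops=0), env, domain
    )
    assert report.controllable
    assert report.per_state["SR"].chain[0].complexity == 0.0


def test_shifted_goal_not_controllable_at_low_capacity(shifted_rep, cfg, env, domain):
    report = is_telic_controllable(
        shifted_rep, cfg, CapacityBound(delta=0.25), HopBudget(n_hops=0), env, domain
    )
    assert not report.controllable
    assert not report.per_state["SR"].reachable
    assert report.per_state["SL"].reachable  # SL is still within 0.25 bits
    # one intermediate hop through an existing state does not help either
    report1 = is_telic_controllable(
        shifted_rep, cfg, CapacityBound(delta=0.25), HopBudget(n_hops=1), env, domain
    )
    assert not report1.per_state["SR"].reachable


def test_empty_goal_state_reported_unreachable(dual_goal, env, domain, cfg):
    rep = build_representation(dual_goal, TelicRule(epsilon=0.999), env, domain)
    report = is_telic_controllable(
        rep, cfg, CapacityBound(delta=10.0), HopBudget(n_hops=1), env, domain
    )
    assert not report.controllable
    assert not report.per_state["SR"].reachable


def test_controllability_monotone_in_delta_and_hops(shifted_rep, cfg, env, domain):
    results = {}
    for delta in (0.25, 0.6, 1.0):
        for n in (0, 1):
            rep = is_telic_controllable(
                shifted_rep, cfg, CapacityBound(delta=delta), HopBudget(n_hops=n),
                env, domain,
            )
            results[(delta, n)] = rep.controllable
    for (d1, n1), c1 in results.items():
        for (d2, n2), c2 in results.items():
            if d2 >= d1 and n2 >= n1 and c1:
                assert c2, f"controllable at ({d1},{n1}) but not ({d2},{n2})"


def test_split_of_reachable_state_is_rejected(dual_rep, cfg, env, domain):
    with pytest.raises(SplitNotNeededError):
        split_state(dual_rep, "SR", cfg, CapacityBound(delta=1.0), env, domain)


def test_split_inserts_intermediate_state_within_capacity(
    shifted_rep, cfg, env, domain
):
    from telic import information_projection

    bound = CapacityBound(delta=0.25)
    new_rep = split_state(shifted_rep, "SR", cfg, bound, env, domain)
    assert new_rep.labels == ["S0", "SR", "SL", "SM"]
    sm = new_rep.state("SM")
    assert sm.n_members > 0
    # the intermediate region sits strictly between the default and R
    assert 0 < sm.anchor.center < 2.5
    proj = information_projection(sm, cfg, env, domain)
    assert proj.complexity <= bound.delta


def test_refinement_terminates_in_one_split_and_verifies(shifted_rep, cfg, env, domain):
    bound = CapacityBound(delta=0.25)
    hops = HopBudget(n_hops=1)
    result = refine_until_controllable(shifted_rep, cfg, bound, hops, env, domain)
    assert result.iterations == 1
    assert result.inserted_states == ["SM"]
    assert len(result.representations) == 2
    final = result.final
    assert sorted(final.labels) == ["S0", "SL", "SM", "SR"]
    # independent re-check of the final representation
    report = is_telic_controllable(final, cfg, bound, hops, env, domain)
    assert report.controllable
    # chain validity: each leg within capacity, length within budget
    for lab, r in report.per_state.items():
        assert 1 <= len(r.chain) <= hops.n_hops + 1
        for hop in r.chain:
            assert hop.complexity <= bound.delta


def test_refinement_noop_when_already_controllable(dual_rep, cfg, env, domain):
    result = refine_until_controllable(
        dual_rep, cfg, CapacityBound(delta=1.0), HopBudget(n_hops=1), env, domain
    )
    assert result.iterations == 0
    assert result.inserted_states == []
    assert result.final is dual_rep


def test_generous_capacity_needs_no_splits(shifted_rep, cfg, env, domain):
    """delta=10 bits exceeds the KL diameter of the bounded grid, so every
    state is reachable directly."""
    import numpy as np

    from telic import policy_complexity_grid

    mu, sd = domain.meshgrid()
    assert policy_complexity_grid(mu, sd, cfg, env).max() < 10.0
    result = refine_until_controllable(
        shifted_rep, cfg, CapacityBound(delta=10.0), HopBudget(n_hops=0), env, domain
    )
    assert result.iterations == 0


def test_split_strictly_grows_the_state_set(shifted_rep, cfg, env, domain):
    new_rep = split_state(
        shifted_rep, "SR", cfg, CapacityBound(delta=0.25), env, domain
    )
    assert len(new_rep.states) == len(shifted_rep.states) + 1
    assert set(shifted_rep.labels) <= set(new_rep.labels)
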