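"""Telic state representations: goal-equivalence classes of policies.

A telic state collects the experience distributions (equivalently, the
policies inducing them) that are interchangeable with respect to a goal.
At sensitivity ``epsilon`` a policy belongs to the state of region ``g``
when its score toward ``g`` is at least ``epsilon`` and no other region
scores higher; all remaining policies form the residual state ``S0``.
The partition is materialized extensionally on a finite (mu, sigma) grid
and intensionally by the score predicate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .goal_functional import GoalSpec, Region, region_score, score_grids
from .policy_model import EnvironmentSpec, PolicyDomain, PolicyParams

RESIDUAL_LABEL = "S0"


class TelicRule(BaseModel):
    """Sensitivity threshold epsilon in (0, 1) defining goal-equivalence."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    epsilon: float = Field(default=0.1, gt=0, lt=1)


def state_label(region_label: str) -> str:
    """Telic-state label for a goal region (R -> SR, M -> SM, ...)."""
    return f"S{region_label}"


@dataclass
class TelicState:
    """One goal-equivalence class, resolved on the representation's grid.

    ``member_mask`` is aligned with PolicyDomain.meshgrid(); ``anchor`` is
    the goal region inducing the state (None for the residual state).
    """

    label: str
    goal_region: str | None
    member_mask: np.ndarray
    anchor: Region | None = None
    goal: GoalSpec | None = None
    epsilon: float | None = None

    @property
    def n_members(self) -> int:
        return int(self.member_mask.sum())

    @property
    def is_residual(self) -> bool:
        return self.goal_region is None


@dataclass
class TelicRepresentation:
    """Partition of the policy domain into telic states plus residual S0."""

    states: list[TelicState]
    goal: GoalSpec
    rule: TelicRule
    domain: PolicyDomain
    env: EnvironmentSpec
    score_arrays: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def state(self, label: str) -> TelicState:
        for s in self.states:
            if s.label == label:
                return s
        raise KeyError(f"no telic state labeled {label!r}")

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.states]

    def goal_states(self) -> list[TelicState]:
        return [s for s in self.states if not s.is_residual]

    def member_counts(self) -> dict[str, int]:
        return {s.label: s.n_members for s in self.states}

    def label_matrix(self) -> np.ndarray:
        """(n_mu, n_sigma) array of state labels (the partition map)."""
        mu, sd = self.domain.meshgrid()
        out = np.full(mu.shape, RESIDUAL_LABEL, dtype=object)
        for s in self.goal_states():
            out[s.member_mask] = s.label
        return out

    def to_json(self, path: str | Path, label_csv: str | Path | None = None) -> None:
        """Serialize rule/goal/domain and per-state counts; optionally dump
        the grid label matrix as CSV aligned to the grid."""
        payload = {
            "rule": json.loads(self.rule.model_dump_json()),
            "goal": json.loads(self.goal.model_dump_json()),
            "domain": json.loads(self.domain.model_dump_json()),
            "env": json.loads(self.env.model_dump_json()),
            "member_counts": self.member_counts(),
            "states": [
                {
                    "label": s.label,
                    "goal_region": s.goal_region,
                    "anchor": None
                    if s.anchor is None
                    else json.loads(s.anchor.model_dump_json()),
                }
                for s in self.states
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        if label_csv is not None:
            import pandas as pd

            lab = self.label_matrix()
            cols = [f"sigma{j}" for j in range(lab.shape[1])]
            pd.DataFrame(lab, columns=cols).to_csv(label_csv, index=False)


def _classify_from_scores(
    scores: dict[str, np.ndarray], order: list[str], epsilon: float
) -> dict[str, np.ndarray]:
    """Masks of the argmax-qualifying region per grid point.

    A point belongs to region g's state when score_g >= epsilon and
    score_g is maximal among all regions (ties broken by the declared
    region order: the earliest label wins).
    """
    stacked = np.stack([scores[lab] for lab in order])
    best = stacked.max(axis=0)
    masks: dict[str, np.ndarray] = {}
    taken = np.zeros(stacked.shape[1:], dtype=bool)
    for i, lab in enumerate(order):
        m = (stacked[i] >= epsilon) & (stacked[i] >= best) & ~taken
        masks[lab] = m
        taken |= m
    return masks


def classify_policy(
    policy: PolicyParams,
    goal: GoalSpec,
    rule: TelicRule,
    env: EnvironmentSpec,
) -> str:
    """Telic-state label of a single policy.

    Returns ``S<g>`` for the best-scoring region g whose score reaches the
    sensitivity threshold, else the residual label ``S0``.  Ties between
    regions are broken by the goal's declared region order.
    """
    best_label: str | None = None
    best_score = -np.inf
    for lab in goal.regions:
        s = region_score(policy, goal, lab, env)
        if s > best_score:
            best_label, best_score = lab, s
    assert best_label is not None
    if best_score >= rule.epsilon:
        return state_label(best_label)
    return RESIDUAL_LABEL


def build_representation(
    goal: GoalSpec,
    rule: TelicRule,
    env: EnvironmentSpec,
    domain: PolicyDomain,
) -> TelicRepresentation:
    """Classify every grid policy and assemble the partition.

    Empty goal states are kept (with zero members) rather than dropped;
    they arise legitimately mid-refinement.
    """
    if domain.size < 1:
        raise ValueError("policy domain grid is empty")
    mu, sd = domain.meshgrid()
    scores = score_grids(goal, env, mu, sd)
    order = list(goal.regions)
    masks = _classify_from_scores(scores, order, rule.epsilon)
    states = [
        TelicState(
            label=state_label(lab),
            goal_region=lab,
            member_mask=masks[lab],
            anchor=goal.regions[lab],
            goal=goal,
            epsilon=rule.epsilon,
        )
        for lab in order
    ]
    residual = TelicState(
        label=RESIDUAL_LABEL,
        goal_region=None,
        member_mask=~np.logical_or.reduce([m.member_mask for m in states]),
    )
    return TelicRepresentation(
        states=[residual] + states,
        goal=goal,
        rule=rule,
        domain=domain,
        env=env,
        score_arrays=scores,
    )


def goal_equivalent(
    p1: PolicyParams, p2: PolicyParams, rep: TelicRepresentation
) -> bool:
    """True iff both policies fall in the same telic state of ``rep``."""
    c1 = classify_policy(p1, rep.goal, rep.rule, rep.env)
    c2 = classify_policy(p2, rep.goal, rep.rule, rep.env)
    return c1 == c2
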