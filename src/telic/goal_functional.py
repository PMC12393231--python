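"""Goals as scalar functionals of experience distributions.

A goal is a preference order over experience distributions.  Here the
order is induced by a scalar score: the probability of reaching the
target region minus the best reach probability among the competing
(core) regions.  Policies with equal scores are goal-equivalent.

Reach semantics default to ``terminal`` (membership of the endpoint x_T
in the region); ``first_passage`` (any of x_1..x_T in the region) is
available through Monte-Carlo estimation only.
"""

from __future__ import annotations

import math
from enum import Enum

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import erf

from .policy_model import (
    EnvironmentSpec,
    PolicyParams,
    endpoint_distribution,
    endpoint_moments_grid,
    sample_trajectories,
)

_SQRT2 = math.sqrt(2.0)

#: score equality tolerance for floating-point rank ties
TIE_TOL = 1e-12


class ReachMode(str, Enum):
    terminal = "terminal"
    first_passage = "first_passage"


class EstimatorMethod(str, Enum):
    analytic = "analytic"
    monte_carlo = "monte_carlo"


class Region(BaseModel):
    """Closed interval [center - width/2, center + width/2] on the line.

    Boundary points count as inside.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    center: float = Field(allow_inf_nan=False)
    width: float = Field(default=1.0, gt=0, allow_inf_nan=False)

    @property
    def lo(self) -> float:
        return self.center - self.width / 2.0

    @property
    def hi(self) -> float:
        return self.center + self.width / 2.0


class GoalSpec(BaseModel):
    """Named goal regions, a target designation and reach semantics.

    ``regions`` is an ordered map label -> Region.  ``core`` lists the
    labels that define the preference score field (competitors); regions
    outside ``core`` are auxiliary intermediate regions added during
    representation refinement and do not alter the scores of the core
    regions.  By default every region is core.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    regions: dict[str, Region]
    target: str
    reach_mode: ReachMode = ReachMode.terminal
    core: tuple[str, ...] | None = None

    @model_validator(mode="after")
    def _validate(self) -> "GoalSpec":
        if self.target not in self.regions:
            raise ValueError(f"target {self.target!r} not among regions")
        core = self.core_labels()
        for lab in core:
            if lab not in self.regions:
                raise ValueError(f"core label {lab!r} not among regions")
        labs = list(self.regions)
        for i, a in enumerate(labs):
            for b in labs[i + 1 :]:
                ra, rb = self.regions[a], self.regions[b]
                if ra.lo <= rb.hi and rb.lo <= ra.hi and {a, b} <= set(core):
                    raise ValueError(f"core regions {a!r} and {b!r} overlap")
        return self

    def core_labels(self) -> tuple[str, ...]:
        return tuple(self.regions) if self.core is None else self.core

    def competitors(self, label: str) -> tuple[str, ...]:
        """Core regions competing against ``label``'s reach probability."""
        return tuple(l for l in self.core_labels() if l != label)

    def with_auxiliary_region(self, label: str, region: Region) -> "GoalSpec":
        """Return a copy with an extra non-core (intermediate) region."""
        if label in self.regions:
            raise ValueError(f"region label {label!r} already present")
        regions = dict(self.regions)
        regions[label] = region
        return GoalSpec(
            regions=regions,
            target=self.target,
            reach_mode=self.reach_mode,
            core=self.core_labels(),
        )


class EstimatorSpec(BaseModel):
    """How reach probabilities are computed."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    method: EstimatorMethod = EstimatorMethod.analytic
    n_mc: int = Field(default=100_000, ge=1)
    seed: int = 0


def _normal_interval_prob(mean, sd, lo: float, hi: float):
    """P(lo <= X <= hi) for X ~ Normal(mean, sd^2), reflection-stable.

    Uses erf (exactly odd in floating point) so that mirrored inputs give
    bit-identical probabilities; ndtr does not have this property.
    """
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return 0.5 * erf(b / _SQRT2) - 0.5 * erf(a / _SQRT2)


def reach_probability(
    policy: PolicyParams,
    region: Region,
    env: EnvironmentSpec,
    mode: ReachMode = ReachMode.terminal,
    est: EstimatorSpec | None = None,
) -> float:
    """Probability of reaching ``region`` under ``policy``.

    ``terminal`` mode is the probability that the endpoint x_T lies in the
    region; analytic evaluation uses the closed-form Gaussian endpoint law.
    ``first_passage`` mode is the probability that any of x_1..x_T lies in
    the region and is Monte-Carlo only.
    """
    est = est or EstimatorSpec()
    if mode is ReachMode.terminal:
        if est.method is EstimatorMethod.analytic:
            g = endpoint_distribution(policy, env)
            return float(_normal_interval_prob(g.mean, g.sd, region.lo, region.hi))
        batch = sample_trajectories(policy, env, est.n_mc, est.seed)
        x = batch.terminal
        return float(np.mean((x >= region.lo) & (x <= region.hi)))
    if est.method is EstimatorMethod.analytic:
        raise ValueError(
            "analytic estimation is unavailable for first_passage reach mode"
        )
    batch = sample_trajectories(policy, env, est.n_mc, est.seed)
    inside = (batch.positions[:, 1:] >= region.lo) & (batch.positions[:, 1:] <= region.hi)
    return float(np.mean(inside.any(axis=1)))


def region_score(
    policy: PolicyParams,
    goal: GoalSpec,
    label: str,
    env: EnvironmentSpec,
    est: EstimatorSpec | None = None,
) -> float:
    """Preference score of ``policy`` with region ``label`` as the target.

    P(label) minus the maximum reach probability over the competing core
    regions (for a single-region goal, just P(label)).
    """
    p = reach_probability(policy, goal.regions[label], env, goal.reach_mode, est)
    comp = goal.competitors(label)
    if not comp:
        return p
    q = max(
        reach_probability(policy, goal.regions[c], env, goal.reach_mode, est)
        for c in comp
    )
    return p - q


def preference_score(
    policy: PolicyParams,
    goal: GoalSpec,
    env: EnvironmentSpec,
    est: EstimatorSpec | None = None,
) -> float:
    """Score of ``policy`` for the goal's designated target region."""
    return region_score(policy, goal, goal.target, env, est)


def rank_policies(
    policies: list[PolicyParams],
    goal: GoalSpec,
    env: EnvironmentSpec,
    est: EstimatorSpec | None = None,
) -> list[tuple[int, PolicyParams, float]]:
    """Sort policies by descending preference score.

    Returns (rank, policy, score) triples; policies whose scores agree
    within ``TIE_TOL`` are goal-equivalent and share a rank (competition
    ranking: 1, 1, 3, ...).
    """
    if not policies:
        raise ValueError("rank_policies requires a non-empty policy list")
    scored = [(p, preference_score(p, goal, env, est)) for p in policies]
    scored.sort(key=lambda t: -t[1])
    out: list[tuple[int, PolicyParams, float]] = []
    for i, (p, s) in enumerate(scored):
        if i > 0 and abs(s - out[-1][2]) <= TIE_TOL:
            rank = out[-1][0]
        else:
            rank = i + 1
        out.append((rank, p, s))
    return out


def score_grids(
    goal: GoalSpec, env: EnvironmentSpec, mu: np.ndarray, sigma: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorized region scores over policy-parameter arrays.

    Returns, for every region label, the analytic terminal-mode score
    array P(label) - max over competing core regions.  The grid surface
    is always evaluated analytically at the terminal endpoint; Monte-Carlo
    and first-passage estimation are available pointwise via
    :func:`reach_probability`.
    """
    mean, sd = endpoint_moments_grid(mu, sigma, env)
    probs = {
        lab: _normal_interval_prob(mean, sd, r.lo, r.hi)
        for lab, r in goal.regions.items()
    }
    out: dict[str, np.ndarray] = {}
    for lab in goal.regions:
        comp = goal.competitors(lab)
        if comp:
            out[lab] = probs[lab] - np.maximum.reduce([probs[c] for c in comp])
        else:
            out[lab] = probs[lab]
    return out
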