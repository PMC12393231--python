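"""Policy complexity as KL divergence from a default policy, and
information projections of the default onto telic states.

Complexity is measured between the Gaussian laws the policies induce,
either at the endpoint level (terminal-position distributions) or at the
trajectory level (T times the single-step KL, which is exact for these
open-loop policies).  The default convention is endpoint level, forward
direction KL(pi || pi0), reported in bits — the capacity bound delta is
quoted in bits in the worked scenarios.

The information projection of the default policy onto a telic state is
the state member of minimal complexity; a state is reachable under a
capacity bound delta when that minimum is at most delta.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .goal_functional import region_score
from .policy_model import (
    EnvironmentSpec,
    PolicyDomain,
    PolicyParams,
    endpoint_distribution,
    endpoint_moments_grid,
    step_distribution,
)
from .telic_representation import TelicRepresentation, TelicState

LOG2 = np.log(2.0)


class KLLevel(str, Enum):
    endpoint = "endpoint"
    trajectory = "trajectory"


class KLDirection(str, Enum):
    forward = "forward"  # KL(pi || pi0)
    reverse = "reverse"  # KL(pi0 || pi)


class KLBase(str, Enum):
    bits = "bits"
    nats = "nats"


class ComplexityConfig(BaseModel):
    """Default policy pi0 and the KL convention defining complexity."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    default_policy: PolicyParams = PolicyParams(mu=0.0, sigma=1.0)
    level: KLLevel = KLLevel.endpoint
    direction: KLDirection = KLDirection.forward
    base: KLBase = KLBase.bits

    def with_default(self, policy: PolicyParams) -> "ComplexityConfig":
        return self.model_copy(update={"default_policy": policy})

    def from_nats(self, value):
        return value / LOG2 if self.base is KLBase.bits else value


class CapacityBound(BaseModel):
    """Maximum complexity (delta) the agent can spend on one leg, in the
    units of the governing ComplexityConfig."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    delta: float = Field(default=1.0, ge=0)


@dataclass
class ProjectionResult:
    """A policy selected within/toward a telic state.

    ``complexity`` is relative to the config's default policy in the
    config's base.  ``feasible`` marks membership of the named state;
    ``distance`` is the KL distance-to-state (0 for members).
    """

    policy: PolicyParams
    complexity: float
    state_label: str
    feasible: bool = True
    distance: float = 0.0

    def to_dict(self) -> dict:
        return {
            "policy": self.policy.model_dump(),
            "complexity": self.complexity,
            "state_label": self.state_label,
            "feasible": self.feasible,
            "distance": self.distance,
        }


@dataclass
class ReachabilityResult:
    reachable: bool
    witness: ProjectionResult | None = None


class EmptyStateError(ValueError):
    """Raised when an operation needs members of an empty telic state."""


def gaussian_kl_nats(mu_p, sd_p, mu_q, sd_q):
    """KL(N(mu_p, sd_p^2) || N(mu_q, sd_q^2)) in nats; vectorized."""
    return (
        np.log(sd_q / sd_p)
        + (np.square(sd_p) + np.square(mu_p - mu_q)) / (2.0 * np.square(sd_q))
        - 0.5
    )


def _level_params(mu, sigma, cfg: ComplexityConfig, env: EnvironmentSpec):
    """Gaussian parameters at the configured distribution level, plus the
    multiplier turning the per-distribution KL into the level's total."""
    if cfg.level is KLLevel.endpoint:
        m, s = endpoint_moments_grid(mu, sigma, env)
        return m, s, 1.0
    step = env.horizon
    # single-step law; trajectory KL is horizon * step KL (i.i.d. steps)
    from .policy_model import ParamConvention

    if env.param_convention is ParamConvention.per_step:
        return np.asarray(mu, dtype=float), np.asarray(sigma, dtype=float), float(step)
    return (
        np.asarray(mu, dtype=float) / step,
        np.asarray(sigma, dtype=float) / np.sqrt(step),
        float(step),
    )


def policy_complexity_grid(
    mu, sigma, cfg: ComplexityConfig, env: EnvironmentSpec
) -> np.ndarray:
    """Vectorized policy complexity over parameter arrays, in cfg.base."""
    mp, sp, mult = _level_params(mu, sigma, cfg, env)
    q = cfg.default_policy
    mq, sq, _ = _level_params(np.float64(q.mu), np.float64(q.sigma), cfg, env)
    if cfg.direction is KLDirection.forward:
        kl = gaussian_kl_nats(mp, sp, mq, sq)
    else:
        kl = gaussian_kl_nats(mq, sq, mp, sp)
    return cfg.from_nats(mult * kl)


def policy_complexity(
    policy: PolicyParams, cfg: ComplexityConfig, env: EnvironmentSpec
) -> float:
    """Complexity of a single policy relative to the default, in cfg.base.

    Zero iff the policy equals the default.
    """
    return float(
        policy_complexity_grid(
            np.float64(policy.mu), np.float64(policy.sigma), cfg, env
        )
    )


def pairwise_kl_grid(
    mu_p, sd_p, mu_q, sd_q, cfg: ComplexityConfig, env: EnvironmentSpec
) -> np.ndarray:
    """KL(p || q) between two policy arrays at the configured level/base.

    Used for chain legs and distance-to-state computations; broadcasting
    applies, so (m, 1) members against (1, a) anchors gives an (m, a)
    leg-complexity matrix.
    """
    mp, sp, mult = _level_params(mu_p, sd_p, cfg, env)
    mq, sq, _ = _level_params(mu_q, sd_q, cfg, env)
    return cfg.from_nats(mult * gaussian_kl_nats(mp, sp, mq, sq))


def mc_policy_complexity(
    policy: PolicyParams,
    cfg: ComplexityConfig,
    env: EnvironmentSpec,
    n: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the complexity: mean log-density ratio
    under the policy's own law.  Returns (estimate, standard error) in
    cfg.base.  Serves as an independent cross-check of the closed form.
    """
    rng = np.random.default_rng(seed)
    q = cfg.default_policy
    if cfg.direction is KLDirection.forward:
        p_pol, q_pol = policy, q
    else:
        p_pol, q_pol = q, policy
    if cfg.level is KLLevel.endpoint:
        gp = endpoint_distribution(p_pol, env)
        gq = endpoint_distribution(q_pol, env)
        x = rng.normal(gp.mean, gp.sd, size=n)
        logr = _normal_logpdf(x, gp.mean, gp.sd) - _normal_logpdf(x, gq.mean, gq.sd)
    else:
        sp = step_distribution(p_pol, env)
        sq = step_distribution(q_pol, env)
        steps = rng.normal(sp.mean, sp.sd, size=(n, env.horizon))
        logr = (
            _normal_logpdf(steps, sp.mean, sp.sd)
            - _normal_logpdf(steps, sq.mean, sq.sd)
        ).sum(axis=1)
    est = float(np.mean(logr))
    se = float(np.std(logr, ddof=1) / np.sqrt(n))
    return float(cfg.from_nats(est)), float(cfg.from_nats(se))


def _normal_logpdf(x, mean, sd):
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - mean) / sd) ** 2


def _lex_argmin(keys: list[np.ndarray]) -> int:
    """Index minimizing the given key arrays lexicographically."""
    order = np.lexsort(tuple(k for k in reversed(keys)))
    return int(order[0])


def _state_member_params(
    state: TelicState, domain: PolicyDomain
) -> tuple[np.ndarray, np.ndarray]:
    mu, sd = domain.meshgrid()
    if not state.member_mask.any():
        raise EmptyStateError(f"telic state {state.label!r} has no grid members")
    return mu[state.member_mask], sd[state.member_mask]


def information_projection(
    state: TelicState,
    cfg: ComplexityConfig,
    env: EnvironmentSpec,
    domain: PolicyDomain,
    polish: bool = False,
    rep: TelicRepresentation | None = None,
) -> ProjectionResult:
    """Member of ``state`` with minimal complexity relative to the default.

    The optimum is found by exhaustive search over the state's grid
    members; ties are broken by smaller |mu - mu0|, then smaller sigma.
    With ``polish=True`` a derivative-free local refinement (Nelder–Mead,
    parameter tolerance 1e-6, capped iterations) is run from the grid
    optimum under a membership penalty; this requires the owning
    representation for the membership predicate and may return an
    off-grid policy.
    """
    mmu, msd = _state_member_params(state, domain)
    comp = policy_complexity_grid(mmu, msd, cfg, env)
    q = cfg.default_policy
    i = _lex_argmin([comp, np.abs(mmu - q.mu), msd])
    best = PolicyParams(mu=float(mmu[i]), sigma=float(msd[i]))
    best_c = float(comp[i])
    if polish:
        if rep is None:
            raise ValueError("polish=True requires the owning representation")
        best, best_c = _polish(best, best_c, state, cfg, env, rep)
    return ProjectionResult(
        policy=best, complexity=best_c, state_label=state.label, feasible=True
    )


def _polish(
    start: PolicyParams,
    start_c: float,
    state: TelicState,
    cfg: ComplexityConfig,
    env: EnvironmentSpec,
    rep: TelicRepresentation,
):
    from scipy.optimize import minimize

    from .telic_representation import classify_policy

    def objective(x):
        mu, sd = x
        if sd <= 0:
            return np.inf
        p = PolicyParams(mu=float(mu), sigma=float(sd))
        if classify_policy(p, rep.goal, rep.rule, rep.env) != state.label:
            return np.inf
        return policy_complexity(p, cfg, env)

    res = minimize(
        objective,
        np.array([start.mu, start.sigma]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 400},
    )
    if np.isfinite(res.fun) and res.fun < start_c:
        return PolicyParams(mu=float(res.x[0]), sigma=float(res.x[1])), float(res.fun)
    return start, start_c


def is_reachable(
    state: TelicState,
    cfg: ComplexityConfig,
    bound: CapacityBound,
    env: EnvironmentSpec,
    domain: PolicyDomain,
) -> ReachabilityResult:
    """Reachable iff the information-projection complexity is <= delta."""
    proj = information_projection(state, cfg, env, domain)
    if proj.complexity <= bound.delta:
        return ReachabilityResult(reachable=True, witness=proj)
    return ReachabilityResult(reachable=False, witness=None)


def distance_to_state(
    mu_cand,
    sd_cand,
    state: TelicState,
    cfg: ComplexityConfig,
    env: EnvironmentSpec,
    domain: PolicyDomain,
    chunk: int = 2048,
) -> np.ndarray:
    """min over state members m of KL(m || candidate), per candidate.

    Computed in chunks to bound memory on fine grids.  Zero for
    candidates that are themselves members.
    """
    mmu, msd = _state_member_params(state, domain)
    mu_cand = np.atleast_1d(np.asarray(mu_cand, dtype=float))
    sd_cand = np.atleast_1d(np.asarray(sd_cand, dtype=float))
    out = np.empty(mu_cand.shape[0])
    for lo in range(0, mu_cand.shape[0], chunk):
        hi = min(lo + chunk, mu_cand.shape[0])
        legs = pairwise_kl_grid(
            mmu[:, None], msd[:, None], mu_cand[None, lo:hi], sd_cand[None, lo:hi],
            cfg, env,
        )
        out[lo:hi] = legs.min(axis=0)
    return out


def nearest_feasible_policy(
    state: TelicState,
    cfg: ComplexityConfig,
    bound: CapacityBound,
    env: EnvironmentSpec,
    domain: PolicyDomain,
    distance: str = "kl",
) -> ProjectionResult:
    """Closest approach to ``state`` within the complexity capacity.

    Over the feasible set {pi : complexity(pi) <= delta} (grid points plus
    the default policy itself, which is always feasible), minimize the
    distance to the state: by default the minimal KL(member || pi) over
    state members, alternatively (``distance="score_shortfall"``) the gap
    epsilon - score(pi) toward the state's region.  Ties are broken by
    smaller complexity, then smaller |mu - mu0|, then smaller sigma.  For
    a reachable state this returns the information projection itself
    (distance 0).
    """
    reach = is_reachable(state, cfg, bound, env, domain)
    if reach.reachable:
        return reach.witness
    mu, sd = domain.meshgrid()
    comp = policy_complexity_grid(mu, sd, cfg, env)
    feas = comp <= bound.delta
    q = cfg.default_policy
    cand_mu = np.append(mu[feas], q.mu)
    cand_sd = np.append(sd[feas], q.sigma)
    cand_comp = np.append(comp[feas], policy_complexity(q, cfg, env))
    if distance == "kl":
        dist = distance_to_state(cand_mu, cand_sd, state, cfg, env, domain)
    elif distance == "score_shortfall":
        if state.goal_region is None:
            raise ValueError("score_shortfall distance needs a goal region")
        dist = np.array(
            [
                max(
                    0.0,
                    (state.epsilon or 0.0)
                    - region_score(
                        PolicyParams(mu=float(m), sigma=float(s)),
                        state.goal,
                        state.goal_region,
                        env,
                    ),
                )
                for m, s in zip(cand_mu, cand_sd)
            ]
        )
    else:
        raise ValueError(f"unknown distance rule {distance!r}")
    i = _lex_argmin([dist, cand_comp, np.abs(cand_mu - q.mu), cand_sd])
    return ProjectionResult(
        policy=PolicyParams(mu=float(cand_mu[i]), sigma=float(cand_sd[i])),
        complexity=float(cand_comp[i]),
        state_label=state.label,
        feasible=False,
        distance=float(dist[i]),
    )
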