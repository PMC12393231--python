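"""Telic controllability and representation refinement by state splitting.

A representation is *telic controllable* for (pi0, delta, N) when every
non-residual telic state can be reached from the default policy pi0 by a
chain of at most N intermediate re-anchorings: each intermediate anchor
is a policy realizing (belonging to) some telic state of the
representation, and every leg of the chain costs at most delta of policy
complexity relative to the previous anchor.  With N = 0 this reduces to
the information-projection test: the state's cheapest member must lie
within delta of pi0.

When a state is out of reach, the representation is refined: the policy
closest to the state within the capacity bound is found, a new
intermediate goal region is inserted at its endpoint mean, and the
default is re-anchored, until the representation becomes controllable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .complexity_projection import (
    CapacityBound,
    ComplexityConfig,
    EmptyStateError,
    ProjectionResult,
    information_projection,
    is_reachable,
    nearest_feasible_policy,
    pairwise_kl_grid,
    policy_complexity,
)
from .goal_functional import Region
from .policy_model import EnvironmentSpec, PolicyDomain, PolicyParams, endpoint_distribution
from .telic_representation import (
    TelicRepresentation,
    build_representation,
    state_label,
)


class HopBudget(BaseModel):
    """Maximum number N of intermediate re-anchorings in a chain."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    n_hops: int = Field(default=1, ge=0)


@dataclass
class StateReachability:
    reachable: bool
    chain: list[ProjectionResult] = field(default_factory=list)


@dataclass
class ControllabilityReport:
    controllable: bool
    per_state: dict[str, StateReachability]

    def to_dict(self) -> dict:
        return {
            "controllable": self.controllable,
            "per_state": {
                lab: {
                    "reachable": r.reachable,
                    "chain": [p.to_dict() for p in r.chain],
                }
                for lab, r in self.per_state.items()
            },
        }


@dataclass
class RefinementResult:
    """Chain of representations and anchors produced by iterative splitting."""

    representations: list[TelicRepresentation]
    anchors: list[PolicyParams]
    inserted_states: list[str]
    iterations: int
    final_report: ControllabilityReport

    @property
    def final(self) -> TelicRepresentation:
        return self.representations[-1]


class SplitNotNeededError(ValueError):
    """Splitting was requested for a state that is already reachable."""


class DegenerateSplitError(RuntimeError):
    """The inserted intermediate state is empty or itself out of reach."""


class NonConvergenceError(RuntimeError):
    """Refinement exhausted its iteration budget; partial result attached."""

    def __init__(self, message: str, partial: RefinementResult | None = None):
        super().__init__(message)
        self.partial = partial


@dataclass
class _Anchor:
    mu: float
    sigma: float
    leg: float  # complexity relative to parent anchor
    parent: int  # index into the anchor list; -1 for the root pi0
    label: str | None  # telic state the anchor realizes (None for pi0)
    level: int


def _member_min_to_anchors(
    mmu: np.ndarray,
    msd: np.ndarray,
    anchors: list[_Anchor],
    cfg: ComplexityConfig,
    env: EnvironmentSpec,
    chunk: int = 1024,
) -> tuple[np.ndarray, np.ndarray]:
    """Per member: (min leg complexity to any anchor, argmin anchor index)."""
    amu = np.array([a.mu for a in anchors])
    asd = np.array([a.sigma for a in anchors])
    best = np.full(mmu.shape[0], np.inf)
    arg = np.zeros(mmu.shape[0], dtype=int)
    for lo in range(0, mmu.shape[0], chunk):
        hi = min(lo + chunk, mmu.shape[0])
        legs = pairwise_kl_grid(
            mmu[lo:hi, None], msd[lo:hi, None], amu[None, :], asd[None, :], cfg, env
        )
        best[lo:hi] = legs.min(axis=1)
        arg[lo:hi] = legs.argmin(axis=1)
    return best, arg


def _backtrack_chain(
    anchors: list[_Anchor], idx: int, terminal: ProjectionResult
) -> list[ProjectionResult]:
    hops: list[ProjectionResult] = [terminal]
    while idx >= 0:
        a = anchors[idx]
        if a.parent == -1 and a.label is None:
            break  # root pi0; not a hop
        hops.append(
            ProjectionResult(
                policy=PolicyParams(mu=a.mu, sigma=a.sigma),
                complexity=a.leg,
                state_label=a.label or "",
                feasible=True,
            )
        )
        idx = a.parent
    hops.reverse()
    return hops


def is_telic_controllable(
    rep: TelicRepresentation,
    cfg: ComplexityConfig,
    bound: CapacityBound,
    hops: HopBudget,
    env: EnvironmentSpec,
    domain: PolicyDomain,
    anchor_mode: str = "member",
) -> ControllabilityReport:
    """Decide reachability of every non-residual state under (pi0, delta, N).

    ``anchor_mode="member"`` (default) lets a chain re-anchor at any grid
    policy belonging to a non-residual telic state; ``"projection"``
    restricts intermediate anchors to the information projections of the
    previous anchor onto the telic states.  Empty goal states are
    reported unreachable.  Every reported chain satisfies: at most N+1
    legs, each leg's complexity (relative to the previous anchor) <= delta.
    """
    if anchor_mode not in ("member", "projection"):
        raise ValueError(f"unknown anchor_mode {anchor_mode!r}")
    delta = bound.delta
    q = cfg.default_policy
    goal_states = rep.goal_states()
    per_state: dict[str, StateReachability] = {}
    mu, sd = domain.meshgrid()

    anchors: list[_Anchor] = [
        _Anchor(mu=q.mu, sigma=q.sigma, leg=0.0, parent=-1, label=None, level=0)
    ]
    pending = {s.label for s in goal_states}

    for level in range(hops.n_hops + 1):
        # resolve states reachable from the current anchor set
        for s in goal_states:
            if s.label not in pending:
                continue
            if not s.member_mask.any():
                continue
            mmu, msd = mu[s.member_mask], sd[s.member_mask]
            best, arg = _member_min_to_anchors(mmu, msd, anchors, cfg, env)
            ok = best <= delta
            if ok.any():
                idx = np.flatnonzero(ok)
                j = idx[np.lexsort((msd[idx], np.abs(mmu[idx] - q.mu), best[idx]))[0]]
                terminal = ProjectionResult(
                    policy=PolicyParams(mu=float(mmu[j]), sigma=float(msd[j])),
                    complexity=float(best[j]),
                    state_label=s.label,
                    feasible=True,
                )
                chain = _backtrack_chain(anchors, int(arg[j]), terminal)
                per_state[s.label] = StateReachability(reachable=True, chain=chain)
                pending.discard(s.label)
        if not pending or level == hops.n_hops:
            break
        # admit the next wave of intermediate anchors
        new_anchors: list[_Anchor] = []
        if anchor_mode == "member":
            for s in goal_states:
                if not s.member_mask.any():
                    continue
                mmu, msd = mu[s.member_mask], sd[s.member_mask]
                best, arg = _member_min_to_anchors(mmu, msd, anchors, cfg, env)
                ok = best <= delta
                for j in np.flatnonzero(ok):
                    new_anchors.append(
                        _Anchor(
                            mu=float(mmu[j]),
                            sigma=float(msd[j]),
                            leg=float(best[j]),
                            parent=int(arg[j]),
                            label=s.label,
                            level=level + 1,
                        )
                    )
        else:
            for ai, a in enumerate(anchors):
                if a.level != level:
                    continue
                a_cfg = cfg.with_default(PolicyParams(mu=a.mu, sigma=a.sigma))
                for s in goal_states:
                    if not s.member_mask.any():
                        continue
                    proj = information_projection(s, a_cfg, env, domain)
                    if proj.complexity <= delta:
                        new_anchors.append(
                            _Anchor(
                                mu=proj.policy.mu,
                                sigma=proj.policy.sigma,
                                leg=proj.complexity,
                                parent=ai,
                                label=s.label,
                                level=level + 1,
                            )
                        )
        if not new_anchors:
            break
        anchors.extend(new_anchors)

    for s in goal_states:
        if s.label in pending:
            per_state[s.label] = StateReachability(reachable=False, chain=[])
    controllable = all(r.reachable for r in per_state.values()) and bool(per_state)
    return ControllabilityReport(controllable=controllable, per_state=per_state)


def _next_intermediate_label(rep: TelicRepresentation) -> str:
    existing = set(rep.goal.regions)
    if "M" not in existing:
        return "M"
    k = 2
    while f"M{k}" in existing:
        k += 1
    return f"M{k}"


def split_state(
    rep: TelicRepresentation,
    target_label: str,
    cfg: ComplexityConfig,
    bound: CapacityBound,
    env: EnvironmentSpec,
    domain: PolicyDomain,
) -> TelicRepresentation:
    """Insert an intermediate telic state toward an unreachable target.

    The nearest feasible policy pi* toward the target is computed; a new
    auxiliary goal region with the target region's width is centered at
    pi*'s endpoint mean, and the representation is rebuilt.  The inserted
    state must be non-empty and its information projection from the
    current default must lie within the capacity bound.
    """
    state = rep.state(target_label)
    if state.is_residual:
        raise ValueError("cannot split the residual state")
    if is_reachable(state, cfg, bound, env, domain).reachable:
        raise SplitNotNeededError(
            f"state {target_label!r} is already reachable within delta={bound.delta}"
        )
    pstar = nearest_feasible_policy(state, cfg, bound, env, domain)
    center = endpoint_distribution(pstar.policy, env).mean
    width = rep.goal.regions[state.goal_region].width
    label = _next_intermediate_label(rep)
    new_goal = rep.goal.with_auxiliary_region(label, Region(center=center, width=width))
    new_rep = build_representation(new_goal, rep.rule, env, domain)
    inserted = new_rep.state(state_label(label))
    if not inserted.member_mask.any():
        raise DegenerateSplitError(
            f"inserted state {inserted.label!r} has no grid members"
        )
    proj = information_projection(inserted, cfg, env, domain)
    if proj.complexity > bound.delta:
        raise DegenerateSplitError(
            f"inserted state {inserted.label!r} is itself out of reach "
            f"({proj.complexity:.4f} > {bound.delta})"
        )
    return new_rep


def refine_until_controllable(
    rep: TelicRepresentation,
    cfg: ComplexityConfig,
    bound: CapacityBound,
    hops: HopBudget,
    env: EnvironmentSpec,
    domain: PolicyDomain,
    max_iter: int = 10,
    reanchor: str = "projection",
    anchor_mode: str = "member",
) -> RefinementResult:
    """Split states until the representation is telic controllable.

    Each iteration: check controllability for the original default; if it
    fails, split the unreachable state whose information projection (from
    the current anchor) is cheapest, then re-anchor the default onto the
    inserted state — either at its information projection
    (``reanchor="projection"``, the default) or at the nearest feasible
    policy itself (``reanchor="nearest"``).  Raises NonConvergenceError
    (with the partial result attached) if the iteration budget is
    exhausted or a split fails to shrink the worst infeasibility gap.
    """
    if reanchor not in ("projection", "nearest"):
        raise ValueError(f"unknown reanchor rule {reanchor!r}")
    reps = [rep]
    anchors = [cfg.default_policy]
    inserted: list[str] = []
    prev_gap: float | None = None
    iterations = 0
    while True:
        report = is_telic_controllable(
            reps[-1], cfg, bound, hops, env, domain, anchor_mode=anchor_mode
        )
        if report.controllable:
            return RefinementResult(
                representations=reps,
                anchors=anchors,
                inserted_states=inserted,
                iterations=iterations,
                final_report=report,
            )
        partial = RefinementResult(
            representations=reps,
            anchors=anchors,
            inserted_states=inserted,
            iterations=iterations,
            final_report=report,
        )
        if iterations >= max_iter:
            raise NonConvergenceError(
                f"not controllable after {iterations} splits", partial=partial
            )
        anchor_cfg = cfg.with_default(anchors[-1])
        unreachable = [
            lab for lab, r in report.per_state.items() if not r.reachable
        ]
        projs = {}
        for lab in unreachable:
            st = reps[-1].state(lab)
            if not st.member_mask.any():
                continue
            projs[lab] = information_projection(st, anchor_cfg, env, domain)
        if not projs:
            raise NonConvergenceError(
                "all unreachable states are empty; cannot split", partial=partial
            )
        gap = max(p.complexity - bound.delta for p in projs.values())
        if prev_gap is not None and gap >= prev_gap:
            raise NonConvergenceError(
                f"split did not reduce the infeasibility gap ({gap:.4f} >= "
                f"{prev_gap:.4f})",
                partial=partial,
            )
        prev_gap = gap
        target = min(projs, key=lambda lab: (projs[lab].complexity, lab))
        new_rep = split_state(reps[-1], target, anchor_cfg, bound, env, domain)
        new_label = new_rep.labels[-1]
        new_state = new_rep.state(new_label)
        if reanchor == "projection":
            new_anchor = information_projection(new_state, anchor_cfg, env, domain).policy
        else:
            new_anchor = nearest_feasible_policy(
                reps[-1].state(target), anchor_cfg, bound, env, domain
            ).policy
        reps.append(new_rep)
        anchors.append(new_anchor)
        inserted.append(new_label)
        iterations += 1
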