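"""Complexity–granularity and goal–complexity tradeoff curves.

The first curve reports, per sensitivity level epsilon, the complexity
of the cheapest policy realizing the target telic state: coarser
representations (smaller epsilon) admit policies nearer the default, so
the required capacity shrinks as the state grows.  The second curve
reports, per capacity delta, the best achievable reach probability of
the target region over the delta-feasible policy set; it grows with
delta and plateaus at the best policy of the bounded domain.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .complexity_projection import (
    ComplexityConfig,
    EmptyStateError,
    information_projection,
    policy_complexity,
    policy_complexity_grid,
)
from .goal_functional import EstimatorSpec, GoalSpec, reach_probability
from .policy_model import EnvironmentSpec, PolicyDomain, endpoint_moments_grid
from .telic_representation import TelicRule, build_representation, state_label
from .goal_functional import _normal_interval_prob


@dataclass
class Curve:
    x: list[float]
    y: list[float]
    x_label: str
    y_label: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")
        if any(b <= a for a, b in zip(self.x, self.x[1:])):
            raise ValueError("x must be strictly increasing")

    def to_csv(self, path: str | Path) -> None:
        """CSV of (x, y) plus a JSON metadata sidecar with full provenance."""
        import pandas as pd

        path = Path(path)
        pd.DataFrame({self.x_label: self.x, self.y_label: self.y}).to_csv(
            path, index=False
        )
        side = dict(self.metadata)
        side["x_label"] = self.x_label
        side["y_label"] = self.y_label
        path.with_suffix(".meta.json").write_text(
            json.dumps(side, indent=2, sort_keys=True, default=str) + "\n"
        )


def complexity_granularity_curve(
    goal: GoalSpec,
    target_label: str,
    cfg: ComplexityConfig,
    env: EnvironmentSpec,
    domain: PolicyDomain,
    epsilons: list[float],
    log_base: str = "e",
) -> Curve:
    """Capacity required to realize the target state, per granularity.

    For each sensitivity epsilon the telic representation is rebuilt and
    the information-projection complexity of the default onto the target
    state recorded against x = -log(epsilon) (natural log by default,
    ``log_base="2"`` for bits of granularity).  The state grows as
    epsilon shrinks (nestedness), so y is non-increasing along x.
    Epsilons whose state is empty yield y = inf and are flagged.
    """
    if any(b <= a for a, b in zip(epsilons, epsilons[1:])):
        raise ValueError("epsilons must be sorted ascending")
    logf = math.log if log_base == "e" else math.log2
    slabel = target_label if target_label.startswith("S") else state_label(target_label)
    xs, ys, empty_eps = [], [], []
    for eps in sorted(epsilons, reverse=True):  # ascending x = -log eps
        rep = build_representation(goal, TelicRule(epsilon=eps), env, domain)
        try:
            proj = information_projection(rep.state(slabel), cfg, env, domain)
            y = proj.complexity
        except EmptyStateError:
            y = math.inf
            empty_eps.append(eps)
        xs.append(-logf(eps))
        ys.append(float(y))
    return Curve(
        x=xs,
        y=ys,
        x_label=f"-log{'' if log_base == 'e' else log_base}(epsilon)",
        y_label=f"projection_complexity_{cfg.base.value}",
        metadata={
            "target_state": slabel,
            "epsilons": list(epsilons),
            "empty_state_epsilons": empty_eps,
            "log_base": log_base,
            "goal": json.loads(goal.model_dump_json()),
            "cfg": json.loads(cfg.model_dump_json()),
            "env": json.loads(env.model_dump_json()),
            "domain": json.loads(domain.model_dump_json()),
        },
    )


def goal_complexity_curve(
    goal: GoalSpec,
    target_label: str,
    cfg: ComplexityConfig,
    env: EnvironmentSpec,
    domain: PolicyDomain,
    deltas: list[float],
) -> Curve:
    """Best reach probability of the target region per capacity level.

    y(delta) maximizes the terminal reach probability over the grid
    policies whose complexity is at most delta, the default policy always
    included; y(0) is therefore the default policy's reach probability
    and the curve is non-decreasing in delta.
    """
    if any(b <= a for a, b in zip(deltas, deltas[1:])):
        raise ValueError("deltas must be sorted ascending")
    if any(d < 0 for d in deltas):
        raise ValueError("deltas must be non-negative")
    region_lab = target_label[1:] if target_label.startswith("S") else target_label
    region = goal.regions[region_lab]
    mu, sd = domain.meshgrid()
    comp = policy_complexity_grid(mu, sd, cfg, env)
    mean, esd = endpoint_moments_grid(mu, sd, env)
    prob = _normal_interval_prob(mean, esd, region.lo, region.hi)
    q = cfg.default_policy
    q_comp = policy_complexity(q, cfg, env)
    q_prob = reach_probability(q, region, env, goal.reach_mode, EstimatorSpec())
    ys = []
    for d in deltas:
        feas = comp <= d
        best = prob[feas].max() if feas.any() else -math.inf
        if q_comp <= d:
            best = max(best, q_prob)
        ys.append(float(best))
    return Curve(
        x=[float(d) for d in deltas],
        y=ys,
        x_label=f"delta_{cfg.base.value}",
        y_label=f"reach_probability_{region_lab}",
        metadata={
            "target_region": region_lab,
            "goal": json.loads(goal.model_dump_json()),
            "cfg": json.loads(cfg.model_dump_json()),
            "env": json.loads(env.model_dump_json()),
            "domain": json.loads(domain.model_dump_json()),
        },
    )


def render_curves(
    curves: list[Curve],
    path: str | Path,
    epsilon_ref: float | None = None,
    delta_ref: float | None = None,
    title: str | None = None,
) -> None:
    """Overlay curves in one PNG with optional dashed reference lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for c in curves:
        finite = [(a, b) for a, b in zip(c.x, c.y) if math.isfinite(b)]
        if not finite:
            continue
        label = c.metadata.get("target_state") or c.metadata.get("target_region")
        ax.plot(*zip(*finite), marker="o", label=str(label))
    if epsilon_ref is not None:
        ax.axvline(-math.log(epsilon_ref), ls="--", color="gray")
    if delta_ref is not None:
        ax.axhline(delta_ref, ls="--", color="gray")
    ax.set_xlabel(curves[0].x_label)
    ax.set_ylabel(curves[0].y_label)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
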