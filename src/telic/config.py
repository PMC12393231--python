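"""Scenario configuration: schema, loading, fixtures and provenance.

A scenario file (YAML or JSON) pins every quantity a run depends on —
environment, goal regions, sensitivity, complexity convention, capacity,
hop budget, policy grid, estimator and seeds — so that any result can be
regenerated bit-for-bit from the file alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .complexity_projection import CapacityBound, ComplexityConfig
from .controllability_refinement import HopBudget
from .goal_functional import EstimatorSpec, GoalSpec, Region
from .policy_model import EnvironmentSpec, PolicyDomain
from .telic_representation import TelicRule

FIXTURE_NAMES = ("dual_goal", "shifted_goal", "tiny_grid")


class ScenarioConfig(BaseModel):
    """Complete, schema-validated description of one scenario."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    env: EnvironmentSpec = EnvironmentSpec()
    goal: GoalSpec
    rule: TelicRule = TelicRule()
    cfg: ComplexityConfig = ComplexityConfig()
    bound: CapacityBound = CapacityBound()
    hops: HopBudget = HopBudget()
    domain: PolicyDomain = PolicyDomain()
    estimator: EstimatorSpec = EstimatorSpec()
    n_trajectories: int = Field(default=500, ge=1)
    seeds: dict[str, int] = Field(default_factory=lambda: {"simulate": 0})
    output_dir: str = "results"

    def canonical_json(self) -> str:
        return json.dumps(
            json.loads(self.model_dump_json()), sort_keys=True, separators=(",", ":")
        )

    def config_hash(self) -> str:
        """Hash of the scientific content (everything except where the
        results are written), so reruns into different directories agree."""
        payload = json.loads(self.model_dump_json())
        payload.pop("output_dir", None)
        canonical = json.dumps(payload, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML/JSON scenario file.

    Unknown keys are rejected; validation failures carry field-level
    messages (pydantic).  An empty file is a schema error.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"scenario file {path} does not contain a mapping")
    return ScenarioConfig.model_validate(raw)


def save_scenario(config: ScenarioConfig, path: str | Path) -> None:
    """Write a scenario as YAML (round-trips identically via load)."""
    payload = json.loads(config.model_dump_json())
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def _dual_goal_base(**overrides) -> ScenarioConfig:
    base = dict(
        env=EnvironmentSpec(horizon=30, start=0.0),
        goal=GoalSpec(
            regions={
                "R": Region(center=2.0, width=1.0),
                "L": Region(center=-2.0, width=1.0),
            },
            target="R",
        ),
        rule=TelicRule(epsilon=0.1),
        cfg=ComplexityConfig(),
        bound=CapacityBound(delta=1.0),
        hops=HopBudget(n_hops=1),
        domain=PolicyDomain(),
        estimator=EstimatorSpec(),
        n_trajectories=500,
        seeds={"simulate": 20300},
    )
    base.update(overrides)
    return ScenarioConfig(**base)


def generate_fixture(name: str, path: str | Path | None = None) -> ScenarioConfig:
    """Build one of the packaged canonical scenarios.

    ``dual_goal``     — horizon 30, unit regions at +2/-2, eps 0.1, delta 1.
    ``shifted_goal``  — as dual_goal but R recentered at 2.5 and delta 0.25,
                        which puts SR out of direct reach and exercises the
                        split path.
    ``tiny_grid``     — dual_goal on a 5x5 policy grid, small enough for
                        exhaustive brute-force checking.
    If ``path`` is given the scenario is also written there as YAML.
    """
    if name == "dual_goal":
        config = _dual_goal_base()
    elif name == "shifted_goal":
        config = _dual_goal_base(
            goal=GoalSpec(
                regions={
                    "R": Region(center=2.5, width=1.0),
                    "L": Region(center=-2.0, width=1.0),
                },
                target="R",
            ),
            bound=CapacityBound(delta=0.25),
        )
    elif name == "tiny_grid":
        config = _dual_goal_base(
            domain=PolicyDomain(
                mu_min=-2.0, mu_max=2.0, n_mu=5, sigma_min=0.5, sigma_max=1.5, n_sigma=5
            )
        )
    else:
        raise ValueError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    if path is not None:
        save_scenario(config, path)
    return config
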