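"""Gaussian random-walk policies and the experience distributions they induce.

An *experience* is a discrete-time 1-D random-walk trajectory
``x_0, x_1, ..., x_T``; a policy is a point ``(mu, sigma)`` in a Gaussian
family that fixes the law of the position increments and hence a
distribution over experiences.  Two step-model conventions are supported:

``per_step``
    each increment is drawn from ``Normal(mu, sigma^2)``, so the terminal
    position is ``Normal(start + T*mu, T*sigma^2)``;
``endpoint``
    each increment is drawn from ``Normal(mu/T, sigma^2/T)``, so ``(mu,
    sigma)`` directly parameterizes the terminal law
    ``Normal(start + mu, sigma^2)``.

The ``endpoint`` convention is the package default: the worked scenarios
place goal regions at terminal displacements of about two units, which is
coherent only if ``mu`` lives on the terminal scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterator

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator


class ParamConvention(str, Enum):
    """How (mu, sigma) map onto the per-step increment law."""

    endpoint = "endpoint"
    per_step = "per_step"


class PolicyParams(BaseModel):
    """A point (mu, sigma) in the Gaussian policy family.

    ``mu`` is the drift parameter and ``sigma`` the dispersion parameter,
    both in position units; their meaning depends on the environment's
    parameter convention.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    mu: float = Field(allow_inf_nan=False)
    sigma: float = Field(gt=0, allow_inf_nan=False)

    def as_tuple(self) -> tuple[float, float]:
        return (self.mu, self.sigma)


class EnvironmentSpec(BaseModel):
    """Fixed environment model: horizon, start position, step convention."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    horizon: int = Field(default=30, ge=1)
    start: float = Field(default=0.0, allow_inf_nan=False)
    param_convention: ParamConvention = ParamConvention.endpoint


class GaussianSpec(BaseModel):
    """Closed-form carrier for a univariate Gaussian law."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    mean: float = Field(allow_inf_nan=False)
    sd: float = Field(gt=0, allow_inf_nan=False)


class PolicyDomain(BaseModel):
    """Rectangular (mu, sigma) grid over which telic states are resolved.

    The grid is the search/test surface for projections and reachability.
    When the mu bounds are symmetric about zero the grid values are
    antisymmetrized so that mirror policies are exact floating-point
    reflections of each other.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    mu_min: float = -3.0
    mu_max: float = 3.0
    n_mu: int = Field(default=301, ge=1)
    sigma_min: float = Field(default=0.5, gt=0)
    sigma_max: float = 2.0
    n_sigma: int = Field(default=151, ge=1)

    @model_validator(mode="after")
    def _check_bounds(self) -> "PolicyDomain":
        if not self.mu_max >= self.mu_min:
            raise ValueError("mu_max must be >= mu_min")
        if not self.sigma_max >= self.sigma_min:
            raise ValueError("sigma_max must be >= sigma_min")
        return self

    @property
    def size(self) -> int:
        return self.n_mu * self.n_sigma

    def mu_values(self) -> np.ndarray:
        m = np.linspace(self.mu_min, self.mu_max, self.n_mu)
        if self.mu_min == -self.mu_max:
            # exact antisymmetry: m[i] == -m[n-1-i] bit-for-bit
            m = (m - m[::-1]) / 2.0
        return m

    def sigma_values(self) -> np.ndarray:
        return np.linspace(self.sigma_min, self.sigma_max, self.n_sigma)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_mu, n_sigma) arrays of mu and sigma values."""
        return np.meshgrid(self.mu_values(), self.sigma_values(), indexing="ij")

    def policies(self) -> Iterator[PolicyParams]:
        for mu in self.mu_values():
            for sd in self.sigma_values():
                yield PolicyParams(mu=float(mu), sigma=float(sd))

    def contains(self, policy: PolicyParams) -> bool:
        return (
            self.mu_min <= policy.mu <= self.mu_max
            and self.sigma_min <= policy.sigma <= self.sigma_max
        )


@dataclass
class TrajectoryBatch:
    """A seeded batch of sampled experiences.

    ``positions`` has shape (n, T+1); column 0 is the start position.
    """

    positions: np.ndarray
    policy: PolicyParams
    env: EnvironmentSpec
    seed: int

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def terminal(self) -> np.ndarray:
        return self.positions[:, -1]

    def to_csv(self, path: str | Path) -> None:
        """Write one row per trajectory (columns t0..tT) plus a JSON sidecar
        carrying the policy/env/seed provenance."""
        import pandas as pd

        path = Path(path)
        cols = [f"t{t}" for t in range(self.positions.shape[1])]
        pd.DataFrame(self.positions, columns=cols).to_csv(path, index=False)
        sidecar = {
            "policy": self.policy.model_dump(),
            "env": json.loads(self.env.model_dump_json()),
            "seed": self.seed,
            "n": self.n,
        }
        path.with_suffix(".json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
        )


def step_distribution(policy: PolicyParams, env: EnvironmentSpec) -> GaussianSpec:
    """Law of a single position increment under the env's convention."""
    if env.param_convention is ParamConvention.per_step:
        return GaussianSpec(mean=policy.mu, sd=policy.sigma)
    T = env.horizon
    return GaussianSpec(mean=policy.mu / T, sd=policy.sigma / math.sqrt(T))


def endpoint_distribution(policy: PolicyParams, env: EnvironmentSpec) -> GaussianSpec:
    """Exact law of the terminal position x_T.

    per_step  -> Normal(start + T*mu, T*sigma^2)
    endpoint  -> Normal(start + mu, sigma^2)
    """
    if env.param_convention is ParamConvention.per_step:
        T = env.horizon
        return GaussianSpec(mean=env.start + T * policy.mu, sd=policy.sigma * math.sqrt(T))
    return GaussianSpec(mean=env.start + policy.mu, sd=policy.sigma)


def endpoint_moments_grid(
    mu: np.ndarray, sigma: np.ndarray, env: EnvironmentSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized endpoint_distribution over arrays of policy parameters."""
    if env.param_convention is ParamConvention.per_step:
        T = env.horizon
        return env.start + T * mu, sigma * math.sqrt(T)
    return env.start + mu, np.asarray(sigma, dtype=float)


def sample_trajectories(
    policy: PolicyParams, env: EnvironmentSpec, n: int, seed: int
) -> TrajectoryBatch:
    """Draw ``n`` seeded random-walk trajectories of length env.horizon."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    step = step_distribution(policy, env)
    rng = np.random.default_rng(seed)
    increments = rng.normal(step.mean, step.sd, size=(n, env.horizon))
    positions = np.empty((n, env.horizon + 1))
    positions[:, 0] = env.start
    np.cumsum(increments, axis=1, out=positions[:, 1:])
    positions[:, 1:] += env.start
    return TrajectoryBatch(positions=positions, policy=policy, env=env, seed=seed)


def mirror_policy(policy: PolicyParams) -> PolicyParams:
    """Reflect a policy's drift about zero: (mu, sigma) -> (-mu, sigma)."""
    return PolicyParams(mu=-policy.mu, sigma=policy.sigma)
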