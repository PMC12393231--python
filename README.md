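# telic

Goal-directed state representations for a 1-D navigation agent: build
*telic states* — equivalence classes of experience distributions that are
interchangeable with respect to a goal — measure the information cost of
realizing them, and repair representations that exceed the agent's
capacity.

The package is aimed at computational cognitive scientists studying
goal-conditioned state abstraction and bounded-capacity policy search,
and at anyone who wants a small, fully reproducible testbed for
information-geometric arguments about goal-directed learning.

## The model

An agent performs a discrete-time 1-D random walk of length `T` starting
at `x_0`. A policy is a point `(μ, σ)` in a Gaussian family; under the
default *endpoint* convention each increment is `Normal(μ/T, σ²/T)`, so
the terminal position is exactly `Normal(x_0 + μ, σ²)` (a *per-step*
convention, increments `Normal(μ, σ²)`, is also supported). Each policy
thus induces a distribution over experiences (trajectories).

A **goal** is a preference order over experience distributions, induced
here by the scalar score

    score(π) = P_π(x_T ∈ R) − max over competing regions P_π(x_T ∈ ·)

for a designated target region `R` (e.g. unit intervals centred at
`x_R = 2` and `x_L = −2`). At sensitivity `ε`, the **telic state** `S_g`
collects the policies whose score toward region `g` is at least `ε` (and
maximal among regions); everything else is the residual state `S0`. The
partition `{S0, S_L, S_R, …}` over a bounded `(μ, σ)` grid is the telic
state representation.

**Policy complexity** is the KL divergence `D(π ‖ π0)` between the laws
induced by a policy and the default policy `π0 = (0, 1)`, in bits. The
**information projection** of `π0` onto a telic state is its cheapest
member; a state is *reachable* under capacity `δ` when that minimum is at
most `δ`. A representation is **telic controllable** for `(π0, δ, N)`
when every goal state can be reached by a chain of at most `N`
intermediate re-anchorings at policies realizing other telic states, each
leg costing at most `δ`. When a state is out of reach, the representation
is refined: a new intermediate region is inserted at the endpoint mean of
the nearest feasible policy, splitting the policy space more finely until
controllability holds.

## Worked example

The shifted-goal scenario moves the right region from 2 to 2.5 and caps
capacity at `δ = 0.25` bits, which puts `S_R` out of direct reach:

```python
from telic import *

scenario = generate_fixture("shifted_goal")
env, cfg, domain = scenario.env, scenario.cfg, scenario.domain

rep = build_representation(scenario.goal, scenario.rule, env, domain)
proj = information_projection(rep.state("SR"), cfg, env, domain)
result = refine_until_controllable(rep, cfg, scenario.bound, scenario.hops,
                                   env, domain)
```

prints (via the accompanying report accessors):

```
states: {'S0': 10700, 'SR': 15488, 'SL': 19263}
projection of pi0 onto SR: mu=0.82 sigma=1.07 complexity=0.4919 bits
reachable at delta=0.25 bits: False
splits: 1 inserted: ['SM']
intermediate region center: 0.56
  SL: reachable=True chain: (-0.40,1.10)@0.129b[SL]
  SM: reachable=True chain: (0.00,1.00)@0.000b[SM]
  SR: reachable=True chain: (0.46,1.27)@0.250b[SM] -> (0.94,1.37)@0.112b[SR]
```

Reading: the cheapest `S_R` member costs 0.4919 bits, nearly twice the
0.25-bit capacity, so `S_R` is unreachable directly. One refinement step
inserts an intermediate state `S_M` centred at 0.56. In the refined
four-state representation the agent reaches `S_R` in two legs — re-anchor
at the `S_M` member (0.46, 1.27) for 0.250 bits, then reach the `S_R`
member (0.94, 1.37) for another 0.112 bits — and every state is within
capacity, so the representation is telic controllable at `N = 1`.

In the original dual-goal scenario (regions at ±2, `δ = 1` bit) no
refinement is needed: the policy (1, 1) is an `S_R` member at
`(Δμ)²/2 = 0.5 nats = 0.72135` bits, and `S_L` mirrors it exactly.

## Command line

Every analysis is also exposed as a subcommand of one executable:

```sh
telic simulate scenario.yaml        # trajectory batch (CSV + provenance)
telic build-states scenario.yaml    # the telic partition (JSON + labels CSV)
telic project scenario.yaml         # projections and reachability
telic controllability scenario.yaml
telic refine scenario.yaml
telic curves scenario.yaml          # tradeoff curves (CSV + metadata)
```

with `--seed` and `--param-convention/--level/--direction/--base`
overrides. Identical configs and seeds produce byte-identical outputs.

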