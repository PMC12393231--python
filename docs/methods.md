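# Methods

## Environment and policy family

The environment is a fixed, known 1-D random walk: horizon `T` (default
30), start position `x_0` (default 0), unbounded positions, no walls or
absorption. Policies are open-loop Gaussian increment laws indexed by
`(μ, σ)`. Two parameter conventions are implemented because the worked
scenarios can be read either way:

- **endpoint** (default): increments are `Normal(μ/T, σ²/T)`, so `(μ, σ)`
  are the mean and sd of the terminal displacement. The scenario
  geometry — goal regions at ±2 and 2.5, interesting policies with
  `μ ≈ 1–2` — only makes sense on the terminal scale, which is why this
  is the default.
- **per_step**: increments are `Normal(μ, σ²)`; the terminal law is
  `Normal(x_0 + T·μ, T·σ²)`.

Everything downstream (scores, KL, projections) consumes the terminal or
step law through one helper, so the convention is a config switch, not a
code path.

## Goals, scores and telic states

A goal names disjoint *core* regions (closed intervals; boundary points
count as inside) and a target. The score of a policy toward region `g`
is `P(x_T ∈ g) − max_{h ≠ g, h core} P(x_T ∈ h)`; for two regions this
is the familiar difference of reach probabilities, and for a one-region
goal it is the plain reach probability. Terminal-mode probabilities are
evaluated analytically from the Gaussian endpoint law; first-passage
probabilities (any of `x_1..x_T` in the region) are Monte-Carlo only.

At sensitivity `ε ∈ (0, 1)` a policy belongs to the telic state of the
region with the highest score, provided that score is at least `ε`
(inclusive); otherwise it falls in the residual state `S0`. Ties between
regions are broken by the declared region order. Because the argmax
condition does not involve `ε`, goal states are nested: raising `ε`
shrinks every state toward its region's best policies.

Intermediate regions inserted during refinement are *auxiliary*: they are
scored against the core regions (`P_M − max(P_R, P_L)`), but they do not
enter the competitor set of the core regions, whose scores — and hence
the goal itself — are unchanged by refinement. Classification is then
argmax over all qualifying regions, so an inserted state carves its
members out of whatever states previously claimed them without
redefining the underlying preference field. This is essential: if the
inserted region were allowed to suppress the scores of the original
states, a split performed under a tight capacity would destroy the very
reachability it is meant to create (the inserted region sits in the
corridor between the default policy and the target, exactly where the
relay policies live).

Representations are materialized extensionally on a rectangular
`(μ, σ)` grid, default 301 × 151 over `μ ∈ [−3, 3]`, `σ ∈ [0.5, 2]` —
fine enough that curve values move by less than 0.02 under a 5× coarser
grid (tested), coarse enough for interactive runtimes. When the μ bounds
are symmetric, the grid values are antisymmetrized so mirrored policies
are exact floating-point reflections. Interval probabilities use
`0.5·(erf(b/√2) − erf(a/√2))`: scipy's `erf` is exactly odd in floating
point, so symmetric scenarios give bitwise-exact mirror symmetry (the
default policy's dual-goal score is exactly 0.0, and `S_L` is the exact
reflection of `S_R`).

## Complexity, projections, capacity

Policy complexity is the closed-form Gaussian KL divergence from the
default policy, with three configurable axes (all are config options
because no single convention is canonical for this construction):

- **level**: endpoint distributions (default) or whole trajectories
  (exactly `T ×` the step-level KL for these open-loop policies);
- **direction**: forward `D(π ‖ π0)` (default; this is what makes the
  minimum over a state an I-projection of `π0`) or reverse;
- **base**: bits (default; capacities are quoted in bits) or nats.

The information projection onto a state is found by exhaustive search
over the state's grid members; ties are broken by smaller `|μ − μ0|`,
then smaller σ. The grid optimum is the canonical, deterministic result
and is what reachability uses; an optional Nelder–Mead polish
(`polish=True`, parameter tolerance 1e-6, capped iterations, membership
enforced by penalty) can refine it off-grid when a continuous optimum is
wanted. A Monte-Carlo log-density-ratio estimator cross-checks the
closed-form KL in the tests.

`nearest_feasible_policy` searches the capacity ball
`{π : D(π‖π0) ≤ δ}` (grid points plus `π0` itself, which is always
feasible) for the policy minimizing the distance to the state, defined
as the minimal forward KL from any state member to the candidate;
a score-shortfall distance (`ε − score`) is available behind a flag.
Ties break by smaller complexity, then `|μ − μ0|`, then σ.

## Controllability and refinement

A representation is telic controllable for `(π0, δ, N)` when every
non-residual state is reachable by a chain `π0 → a_1 → … → a_k` with
`k ≤ N + 1`, each `a_i` (for `i < k`) a grid policy belonging to some
non-residual telic state, the final policy a member of the target state,
and every leg costing at most `δ` (KL of the new anchor from the
previous one, at the configured level/base). At `N = 0` this reduces to
the information-projection test. Intermediate anchors are *members* of
telic states rather than only the states' information projections: the
agent re-anchors at whichever policy realizes the intermediate state
best serves the onward leg. The projection-only variant is available as
`anchor_mode="projection"`, but it is degenerate whenever the default
policy is itself a member of the intermediate state (the projection is
then `π0` and the chain cannot advance), which is the typical situation
after a split under a tight capacity. Reachability is computed by
feasible-set propagation on the grid with chunked pairwise-KL minima;
witness chains are reconstructed by argmin backtracking.

Refinement (`refine_until_controllable`) repeats: check controllability;
among unreachable states pick the one whose information projection from
the current anchor is cheapest; compute the nearest feasible policy
toward it; insert an auxiliary region of the target's width centred at
that policy's endpoint mean; rebuild; re-anchor the default onto the
inserted state (at its information projection by default, or at the
nearest-feasible policy itself with `reanchor="nearest"`). A split must
produce a non-empty intermediate state whose projection is within
capacity, and successive splits must shrink the worst infeasibility gap;
otherwise the run aborts with a non-convergence error carrying the
partial result. The iteration cap defaults to 10.

In the shifted scenario (right region at 2.5, `δ = 0.25` bits,
`N = 1`) this terminates after exactly one split: the inserted state is
centred at 0.56, and the final four-state representation passes an
independent controllability check with every chain leg within capacity.

## Tradeoff curves

- **Complexity–granularity**: for each `ε` the representation is rebuilt
  and the projection complexity onto the target state recorded against
  `x = −log ε` (natural log by default; the base is recorded in the
  metadata). By nestedness the required capacity is non-decreasing in
  `ε`, i.e. non-increasing along `x`; as `ε → 0` the state's closure
  approaches the half-plane of positive scores, which touches the
  default policy, so the curve vanishes. Empty states yield `+inf`
  points, flagged in the metadata rather than dropped.
- **Goal–complexity**: for each capacity `δ` the best terminal reach
  probability of the target region over the `δ`-ball (grid plus the
  default policy) is recorded. It starts at the default policy's own
  reach probability at `δ = 0` and plateaus at the bounded grid's best
  policy once `δ` exceeds the grid's KL diameter.

Both curves carry full provenance (goal, convention, grid, seeds) in a
JSON sidecar sufficient to regenerate them bit-for-bit.

## Scenarios and determinism

Three packaged scenarios: `dual_goal` (regions at ±2, `ε = 0.1`,
`δ = 1` bit, `N = 1`, 500 trajectories of length 30), `shifted_goal`
(right region at 2.5 and `δ = 0.25` bits, chosen to force the split
path), and `tiny_grid` (a 5 × 5 policy grid small enough for exhaustive
brute-force verification of the projection operators under all eight
complexity conventions). All randomness flows through named seeds in the
scenario file; repeated runs with identical config and seeds are
byte-identical (result files carry a hash of the scientific config,
excluding the output directory).

## What the synthetic scenarios do and do not show

The generator emulates exactly the idealized study conditions: open-loop
Gaussian policies, a fixed known environment, scalar-score goals over
terminal positions. Passing tests therefore demonstrate the internal
consistency of the construction (projection optimality, symmetry,
nestedness, chain validity), not its adequacy for closed-loop policies,
state-dependent noise, non-Gaussian dynamics, or goals that are genuine
preference orders not representable by a scalar score — all of which are
out of scope. Known further limitations: telic states are resolved only
on the bounded grid (continuous boundaries are approximated), refinement
splits only by inserting regions along μ (never along σ or arbitrary
score level-sets), and the repair is greedy rather than
minimum-number-of-splits optimal.
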