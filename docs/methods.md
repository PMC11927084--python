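# Methods

## Model

A population of N individuals is split into two static groups, blue
(label 0) and red (label 1), with red fraction r. Each individual v
holds a binary choice H(v) ∈ {0, 1}. At each discrete step a node X is
drawn uniformly at random (with replacement) and recomputes its choice
from the composition of its neighborhood. Writing d^{in,1}, d^{in,0},
d^{out,1}, d^{out,0} for the fractions of X's neighbors by (group
match, current choice), the signed social drive is

    g(X) = α (d^{in,1} − d^{in,0}) − β (d^{out,1} − d^{out,0}),

with α the in-group-love (conformity) weight, β the out-group-hate
(opposition) weight, both in [0, 1]. The node adopts choice 1 when
g > δ, choice 0 when g < −δ, and keeps its current choice otherwise;
δ ∈ [0, 1] is the inertia threshold, and the inequalities are strict
(a drive exactly at ±δ never changes a choice — compared exactly, no
epsilon). The rule is undefined for degree-0 nodes: the updater raises
an error, and the scheduler skips isolated nodes only when explicitly
told to tolerate them, with a logged warning.

The system state is the pair θ = (θB, θR) of per-group choice-1
fractions, always ordered (blue, red).

## Mean-field limit

On a fully connected graph the neighborhood fractions reduce to
population fractions, and for large N the rescaled process θ(t = k/N)
approaches the piecewise-smooth ODE: per group, θ̇ = (1 − θ) while the
group drive exceeds δ, θ̇ = −θ while it is below −δ, and θ̇ = 0 in
between, with affine drives

    gB = a·(2θB − 1) − b·(2θR − 1),   a = α_e (1 − r),  b = β_e r,
    gR = c·(2θR − 1) − d·(2θB − 1),   c = α_e r,        d = β_e (1 − r).

The red drive carries the red in-group size factor r in the conformity
term, mirroring the blue drive's (1 − r); the variant without that
factor is available behind `MeanFieldConfig(red_drive="printed")` for
comparison but does not reproduce the phase boundaries below and is not
used anywhere else.

On a two-block graph where within-group pairs connect with probability
ρ and cross-group pairs with 1 − ρ (ρ = homophily), the same ODE
applies with the effective weights α_e = αρ, β_e = β(1 − ρ); fully
connected mode uses α_e = α, β_e = β. At ρ = 0.5 both drives are
exactly halved (an exact power-of-two rescaling in floating point), so
with δ = 0 every indicator — hence the whole trajectory — is
bit-identical to the fully connected one. For δ > 0 the rescaling
shrinks the drives while δ stays fixed, so block-model results with
inertia are an approximation: the substitution is applied before the δ
comparison (the exact block-model equation is outside this package's
scope).

### Regimes

The long-run outcome from a party-independent start θB(0) = θR(0) ≠ 0.5
at δ = 0 is decided by the two corner drives

    p = α_e (1 − r) − β_e r        (blue drive at the (1,1) corner),
    q = α_e r − β_e (1 − r)        (red drive at the (1,1) corner):

- p > 0, q > 0 (equivalently β_e/α_e < r/(1−r) < α_e/β_e): **case 1**,
  consensus — both groups adopt the initially popular choice; (1,1) and
  (0,0) are the stable limits.
- p < 0, q > 0: **case 2**, partisan split — the red majority keeps the
  initially popular choice, blue adopts the other ((0,1) from above
  0.5, (1,0) from below).
- p > 0, q < 0: **case 3**, the blue-majority mirror of case 2.
- p < 0, q < 0: **case 4**, nonpartisan split — the state decays to
  (0.5, 0.5), an unstable stationary point.
- p = 0 or q = 0: non-generic boundary (reported as such; classified
  with a 1e-12 relative tolerance).

`limiting_state` returns these closed-form limits for diagonal δ = 0
starts and integrates to convergence otherwise. Note that the case-4
trajectory from a diagonal start reaches (0.5, 0.5) in *finite* time
(θ(t) = θ(0)e^{−t} until θ = 0.5, then exactly frozen): the decay
branch of the ODE is θ̇ = −θ, not a relaxation toward 0.5.

### Consensus reachability (δ = 0)

From a party-dependent start, consensus at (1,1) (resp. (0,0)) is
reached iff the regime is case 1 and both drives are strictly positive
(resp. negative) at θ(0). The shared-sign cone is flow-invariant in
case 1: along the flow, gB obeys dgB/dt = [a − b] − gB when blue is
active, so with p = a − b > 0 the blue drive can never reach 0 from
above (symmetrically for red with q > 0); if the signs disagree they
stay disagreeing (each inactive-side drive moves monotonically away
from zero) and the state polarizes. Cross-multiplied, the condition is
the ratio bound β_e r/(α_e(1−r)) < (2θB(0)−1)/(2θR(0)−1) <
α_e r/(β_e(1−r)) for same-sign coordinates; the implementation uses the
drive signs directly, avoiding any division. The checker is validated
against an integrate-to-convergence oracle on a 21×21 grid of initial
states for 20 random case-1 configurations (cells within 1e-3 of a
switching manifold excluded); agreement is exact.

### Event-driven integration

Within a region of constant drive signs each component relaxes in
closed form, θ(t) = T + (θ(t₀) − T) e^{−(t−t₀)} with target T ∈
{1, 0, θ(t₀)}, so each drive is A + B e^{−τ} and region exits solve
A + B e^{−τ} = ±δ exactly (τ = −ln((±δ − A)/B)). The integrator chains
segments at these events; sampling any time inside a segment is exact
evaluation, so the only error source is floating-point round-off. A
drive landing exactly on ±δ yields zero rate under the strict
inequalities; whether the component stays frozen or immediately
re-enters an active region is resolved by the sign of the drive's time
derivative with the component held frozen (for this model the
component's own motion always reinforces its active direction, so no
genuine sliding mode can occur with α, β ≥ 0; a fully degenerate
derivative freezes the component and records a `freeze` event).
Numerical guards: boundary tolerance 1e-12 on drive comparisons,
minimum event spacing 1e-12 in time, `max_events` = 1000 (exceeding it
raises a diagnostic error rather than silently chattering). Default
horizon 40 (≥ 17 e-foldings from any interior start; convergence
tolerance for limiting states 1e-9).

`switching_manifolds` returns the four affine loci gB = ±δ, gR = ±δ in
the (θB, θR) unit square — the tipping lines where a group's trend can
reverse; at δ = 0 each group's pair of lines coincides and passes
through (0.5, 0.5), with blue slope dθR/dθB = a/b.

## Agent-based model

Updates sample nodes uniformly with replacement (the paper's sequential
rule; no shuffled sweeps). Group fractions are tracked incrementally
and recorded every `record_every` steps (default N/20) on the rescaled
axis t = k/N — one mean-field time unit per N steps, since the expected
per-step change of a group fraction is O(1/N). The inner loop is a
numba-compiled kernel over CSR adjacency; the pure-Python
`update_choice` is the reference semantics, and a replay test checks
the kernel reproduces it node for node. Absorption is detected by a
full stability sweep every N steps (no node's update could change its
choice) — never by "no recent flips", which would misreport frozen-but-
mixed δ > 0 states; absorbed runs pad their remaining record grid with
the absorbed state so replicates share a common grid. Default
`max_steps` = 30 N.

Ensembles spawn per-run substreams from the master seed
(`SeedSequence.spawn`, recorded in metadata) and report pointwise means
with 95% bands as empirical 2.5/97.5 percentiles across runs — robust
at the standard 50-replicate design and calibrated against a binomial
toy process in the tests (~95% coverage of a fresh replicate).

`detect_reversal` uses the exact region-switch events for mean-field
trajectories; for sampled stochastic trajectories it smooths the
increment sequence with a moving average (default window 5) and reports
sign changes whose smoothed magnitude exceeds `min_amp` on both sides.

## Graphs, labels, assortativity

Generators: complete graphs, binomial (Erdős–Rényi-like) graphs, and
two-block SBMs with within/cross edge probabilities c·ρ and c·(1−ρ).
The global density multiplier c is exposed because the literal
"probability ρ" produces near-dense graphs at any size, while with
δ = 0 the dynamics depend on neighborhood composition ratios, not
density; recipe stand-ins default to mean degree ≈ 20 (c = 40/N).
Sampling is vectorized seeded Bernoulli over the upper-triangle pair
indices, so arbitrary label vectors (not just contiguous blocks) are
respected.

Party assortativity is the standard Newman categorical assortativity
over the 2×2 edge mixing matrix, (tr e − Σ(e²)) / (1 − Σ(e²));
it is cross-checked in tests against both a literal mixing-matrix
accumulation and networkx's attribute assortativity to 1e-12.
Assortativity-targeted assignment starts from a uniformly random
assignment with exactly round(rN) red nodes and anneals red/blue pair
swaps (which preserve the group counts exactly) toward
|achieved − target| = 0; the mixing counts are updated incrementally per
swap, the temperature is geometric from 2e-3 to 1e-6 over 2·10⁵
proposals (set on the scale of a single swap's assortativity change),
and failure to reach the target within the default tolerance 0.02
raises an error reporting the best value achieved (e.g. strongly
negative targets on a complete graph, whose assortativity is fixed by
group sizes).

Edge lists use the plain-text SNAP dialect (two whitespace-separated
integer ids per line, `#` comments); arbitrary ids are remapped to
contiguous 0-based ids with the mapping kept on the graph and
optionally persisted as CSV. Self-loops are dropped with a warning;
duplicate and reversed pairs are merged; malformed lines report their
line number.

## What the synthetic generators emulate — and what they do not

The two-block SBM stand-ins reproduce the features the model's theory
actually depends on: the two-community partition, the homophily level
(within/cross edge-rate ratio ρ/(1−ρ)), the group-size split r, and
enough density that neighborhood fractions concentrate. They do **not**
reproduce heavy-tailed degree distributions, triadic clustering,
core–periphery structure, or the many small communities of real social
networks (the real Facebook/Brightkite datasets named in the experiment
recipes are optional inputs, never downloaded). Passing tests on
stand-ins therefore demonstrate the mean-field mechanism and the
machinery, not that real networks converge at the same rate or to the
same residual gap — on real topologies the group fractions typically
become stationary slightly short of the corners, as the recipes'
endpoint-gap reports are designed to quantify.

## Study conditions and problem sizes

Representative parameter sets: case 1 (α, β, r) = (0.8, 0.4, 0.5),
case 2 (0.6, 0.5, 0.65), case 3 (0.6, 0.5, 0.35), case 4
(0.3, 0.9, 0.5), started from (0.8, 0.8); homophily-flip design
α = 0.8, β = 0.7, r = 0.65 with ρ ∈ {0.7, 0.5}; assignment experiment
α = 0.7, β = 0.5, r = 0.53 with assortativity targets
{0.58, 0.00, −0.13}. Ensembles default to 50 replicates.

The stochastic/deterministic agreement check runs 20 replicates on
complete graphs of N = 5000 over t ∈ [0, 10] per case (measured
sup-norm gaps of the ensemble mean: 0.001–0.005). The case-4 comparison
starts from the party-dependent state (0.8, 0.3): a party-independent
case-4 start passes through the unstable half-half point, where
stochastic paths necessarily break symmetry away from the frozen
deterministic trajectory — the instability is the model's own
prediction, so the comparison is made along a deterministic branch of
the flow instead. The recipe smoke tests run stand-ins at N = 300 with
3 replicates; the full-scale designs are a flag away (`--n-nodes`,
`--n-runs`).

## Known limitations

- The block-model mean field for δ > 0 uses the α→αρ, β→β(1−ρ)
  substitution before the δ comparison (approximation; see above).
- Binary choices, two groups, static parameters and static topology
  only; no weighted or directed edges.
- The annealer targets a scalar assortativity; it does not control
  higher-order mixing structure, so two assignments with equal
  assortativity can still differ in dynamics on structured graphs.
- Closed-form basin boundaries are only provided for δ = 0; for δ > 0
  reachability questions must go through the integrator.
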