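# Methods

## Model and dynamics

`spinflow` studies binary-state dynamics on a connected, simple, undirected
graph. The energy of a configuration `S ∈ {0,1}^n` is the zero-field
ferromagnetic Ising Hamiltonian `E(S) = −J Σ_{(i,j)∈E} σ_i σ_j` with
`σ = 2s − 1` and coupling `J > 0` (default 1). The zero-field choice is what
produces the symmetric bistability the whole analysis rests on: the
stationary distribution is invariant under complementing every node state,
so the two aligned macrostates are equally deep attractors. An external
field or per-edge weights would break that symmetry and are deliberately out
of scope.

Time is discrete and asynchronous: per step, one node is chosen uniformly
at random and flips with the Glauber probability
`p = 1/(1 + exp(−β ΔE))`, where `ΔE = E(old) − E(new)` is the energy the
flip releases. The sign convention makes energy-lowering flips more likely
than 1/2, which is required for the attractors to be sticky and for the
domino ordering (low-degree nodes flip first). One flip per step is the only
update scheme consistent with the 5-step path census on the 10-node kite
(10·9·8·7·6 = 30,240 orderings); the non-flip mass sits on the diagonal of
the transfer operator, which conserves probability exactly.

The inverse temperature is an input. The reference analyses use β = 0.534
with J = 1, a value in the bistable-but-active regime of the kite: the
barrier is high enough that transitions are rare, low enough that a
10^5-attempt chain still crosses it dozens of times. No automatic
calibration of β is performed.

## Exact computation

For `n ≤ 14` (configurable cap; memory guard) the full `2^n × 2^n` row-
stochastic transfer operator is built densely. Configurations are encoded
little-endian: node i (in sorted label order) contributes bit i of the
state index. The stationary distribution is obtained by a direct linear
solve (one balance equation replaced by normalization) with an L1 residual
check at 1e−10 and a power-iteration fallback; the direct solve is the
default because bistability makes the spectral gap — and hence power
iteration — painfully small. Detailed balance of Glauber dynamics implies π
is the Boltzmann distribution, which the tests exploit as an independent
oracle rather than assuming it in the implementation.

The macrostate ⟨S⟩ (fraction of nodes in state 1) partitions the state
space into levels γ ∈ {0, 1/n, …, 1}. The time-0 ensemble "at distance γ
from the tipping point" is π restricted to the level and renormalized. This
is the simplest grouping that needs no extra model; it assumes the system
reached that distance along typical (stationary-weighted) routes, which for
paths that cross several levels in quick succession is an approximation.

## Information flows

For node i and level γ the flow curve is
`I(s_i^0 : S^t | ⟨S^0⟩ = γ)` in bits, for lags t = 0..τ_max (default
τ_max = 300, Δt = 1). Base-2 logarithms give the clean bound of 1 bit at
lag 0. The computation propagates, per level, one marginal row and one
sub-probability row per node through the operator — a single
`(n+1) × 2^n by 2^n × 2^n` product per lag — so all nodes share the matrix
work. Degenerate levels where a node's state is constant (γ = 0 or 1)
produce exact-zero curves by construction, not an error.

**Asymptotic information ω** is estimated as the mean of a curve over its
final 20% of lags (configurable `tail_fraction`; lags 241–300 at the
default horizon), clipped below at zero. Three conditioning modes exist:

* `stationary` (default): ω(s_i) is the tail of the *unconditioned* curve,
  whose time-0 ensemble is π itself. This is the operative notion of
  long-term memory — how much a node's state says about which attractor the
  system occupies — and it is the mode that separates roles: on the kite,
  ω ranges from 0.565 (hub) down to 0.018 (tail tip). It is also the mode
  consistent with μ's definition subtracting a single, level-independent
  ω(s_i).
* `per-level`: each level's curve subtracts its own tail estimate. Useful
  descriptively; the per-level tails are always computed and exposed
  (`omega_per_level`) because their rise toward the tipping level is the
  early-warning signal.
* `shared`: one ω per node, the maximum per-level tail. Kept as an option,
  but note that near the tipping level *every* node's conditional plateau
  is high (even the tail's state predicts the future attractor there, albeit
  with opposite sign), so this mode cannot separate hubs from tails and
  yields role scores clustered near zero.

The true t → ∞ limit of every MI curve is zero for an ergodic finite chain;
ω measures an intermediate-time plateau that exists because attractor
lifetimes far exceed the 300-step horizon. The tail-window mean is a
deliberate, simple estimator of that plateau; a longer horizon lowers ω
slightly and raises μ correspondingly.

**Integrated mutual information** is the truncated sum
`μ(s_i|γ) = Σ_{t=0}^{τ_max} (I(t) − ω(s_i)) Δt`. It can be negative when a
node's conditional curve sits below its stationary plateau (typical for
core nodes far from tipping — their attractor memory exceeds their
conditional excess); negative values are informative for ranking and are
reported as-is.

**Roles.** μ* clips μ at zero and divides by the global maximum over
(node, level); ω* divides the per-node ω by its maximum over nodes. Both
therefore lie in [0, 1] and attain 1, making
`r_i = max_γ μ*(s_i|γ) − max_γ ω*(s_i)` a score in [−1, 1]. Labels use the
natural threshold at 0; the continuous score is always reported, and an
all-zero μ and ω table raises a degenerate-normalization error rather than
inventing a scale.

## Path analysis

Tipping trajectories are fixed-length state sequences from a start
configuration into a target γ level, each step a single-node flip with
positive probability; a flag admits stay-steps for queries longer than the
minimal flip count. Scores are summed logs of full transfer-operator
entries (including the uniform 1/n node-choice factor); since every
enumerated trajectory has the same length, the 1/n factors shift all
objectives equally and the maximizer set is unaffected. Conditioning the
step probabilities on the endpoint (bridge dynamics) would shift every
objective by the same constant, so raw step probabilities are used. Ties
are detected in log space with absolute tolerance 1e−9: maximizers related
by a graph automorphism are exactly tied, and on the kite the maximum is
attained by all admissible orderings of three flip-sets — 12 trajectories —
whose per-step energy releases form the identical multiset {−6, −2, −2,
−2, 0}. The tie is exact for any single-flip rule that depends on the local
field only, at any β.

Commitment probabilities start from π restricted to the tipping level
(⟨S⟩ = 1/2, even n required), evolve a fixed horizon (default 10 steps),
and report, per initial node state, the probability mass of macrostates
above, below, and exactly at the tipping level. Global flip symmetry makes
p(above | s_i = 1) = p(below | s_i = 0), which the tests check.

## Monte Carlo simulator and interventions

The sampler runs the same single-flip dynamics as a sampled chain. All
randomness (initial states, node choices, acceptance uniforms) is drawn
up-front from a seeded PCG64 generator, so traces are bit-identical for a
given seed whether or not the optional numba kernel is available. Time is
counted in node-update attempts; the macrostate is recorded per attempt and
compacted to one sample per sweep (n attempts). Pinning freezes one node at
state 0 and removes it from the update pool while its field still acts on
neighbours — the standard causal clamp.

A *successful metastable transition* is a strict side-to-side crossing of
the tipping level with hysteresis: grazing ⟨S⟩ = 1/2 neither counts nor
resets the side, so a graze followed by retreat is not double-counted.

The intervention experiment runs, per seed, a control plus one arm per
pinned node (default: the top initiator and the top stabilizer from the
role table), with identical step budgets, and reports seed-averaged
transition counts plus control-normalized ratios of the macrostate
fluctuation second moment (variance of the sweep trace) and of the fraction
of time spent below the tipping level. Normalization is per graph, with the
control of the same graph and seed set. The ensemble study samples
connected Erdős–Rényi graphs G(10, 0.2) by rejection, computes roles
exactly per graph (levels up to the tipping point only — flip symmetry
makes the upper half redundant), and compares initiator-pinned to
stabilizer-pinned transition counts across graphs.

Problem sizes used by the shipped analyses: τ_max = 300 with 6 levels on
the kite; 100,000 attempts per simulation arm with 6–8 seeds; 20 ER graphs
in the ensemble. These scales make every qualitative effect reproducible in
minutes on one core; the directional pinning result is decisive at this
scale (20/20 graphs, sign-test p ≈ 10⁻⁶).

## What the built-in generators do and do not emulate

The kite fixture and G(n, p) sampler reproduce the study systems exactly
(small graphs, binary states, homogeneous coupling). They do not emulate
weighted or directed interactions, external fields, degree distributions of
large real networks, or observational noise; conclusions from passing tests
therefore concern the mechanism — noise injection by weakly constrained
nodes, memory storage by well-connected ones — not any particular empirical
network. Exact computation is capped near n = 14 by the 2^n state space;
beyond that only the Monte Carlo simulator applies, and MI-flow estimation
from samples is out of scope.

## Numerical choices

* Stationary solve residual 1e−10 (L1); detailed-balance and symmetry
  invariants checked at 1e−10.
* MI values can undershoot zero by ~1e−15 from floating cancellation; the
  data-processing monotonicity check allows 1e−9.
* Trajectory tie tolerance 1e−9 in log units (exact ties are equal to
  ~1e−13 after float accumulation in different orders).
* Stationary-distribution clipping at zero before renormalization guards
  against −1e−18-scale solver residue.
* The ER sampler retries up to 1000 seeds derived from the input seed; p = 0
  with a connectivity requirement fails loudly.

## Known limitations

* ω's tail-window estimator is horizon-dependent; reported μ and ω are
  meaningful relative to the stated τ_max, not as horizon-free limits.
* The level partition attributes information to the distance coordinate
  only; path-history effects within a level are averaged out.
* Role scores compress two curves into one number; nodes like the kite's
  node 8 (high μ *and* substantial tipping-level plateau) sit mid-scale,
  and the initiator/stabilizer labels at the r = 0 threshold are coarse for
  such borderline nodes.
* Synergy/redundancy decompositions of the conditional information are not
  computed.
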