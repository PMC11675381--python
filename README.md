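# spinflow

Information-theoretic dissection of noise-induced transitions in networked
spin systems: exact Glauber dynamics on small graphs, per-node
mutual-information flow curves, initiator/stabilizer role scores,
tipping-path enumeration, and causal pinning interventions.

## The problem

Networks of bistable units — neuronal assemblies, opinion groups, climate
subsystems — can flip between collective states with no external forcing:
fluctuations alone occasionally carry the whole system across a tipping
point. `spinflow` is for researchers who want to know *which nodes make that
happen*. It quantifies each node's contribution with two information
features and validates the resulting role assignment by causal intervention.

## Model

Each node carries a binary state `s_i ∈ {0, 1}` on an undirected graph. With
spins `σ_i = 2s_i − 1`, interactions follow the zero-field ferromagnetic
Ising Hamiltonian

```
E(S) = −J Σ_{(i,j)∈E} σ_i σ_j ,
```

and dynamics are asynchronous Glauber: per time step one uniformly chosen
node flips with probability

```
P(s_i → s_i') = 1 / (1 + exp(−β ΔE)),    ΔE = E(old) − E(new),
```

so energy-releasing flips are favoured and the inverse temperature β sets
the noise level. For n ≤ 14 nodes the full 2^n × 2^n one-step transfer
operator is built exactly; its stationary distribution π (the Boltzmann
distribution, by detailed balance) is bistable at the reference β = 0.534,
with a free-energy barrier at magnetization ⟨S⟩ = 1/2 — the tipping point.

Conditioning π on the distance-to-tipping level γ (fraction of nodes in
state 1) gives per-node information-flow curves
`I(s_i^τ : S^{τ+t} | ⟨S^τ⟩ = γ)` over lags t = 0..τ_max. Each curve is
summarized by

* **μ(s_i|γ)** — integrated mutual information, `Σ_t (I(t) − ω(s_i)) Δt`:
  the short-lived "working memory" a node injects;
* **ω(s_i)** — asymptotic information, the long-lag plateau of the node's
  MI curve from the stationary ensemble: memory of which attractor the
  system occupies;
* **r_i = max_γ μ*(s_i|γ) − max_γ ω*(s_i) ∈ [−1, 1]** (stars denote
  max-normalization) — the role score: **initiators** (r → +1) propagate
  noise toward the tipping point, **stabilizers** (r → −1) hold the system
  in its attractor.

## Worked example

```python
import numpy as np
import spinflow as sf

system = sf.SpinSystem(graph=sf.make_kite(), beta=0.534)
operator = sf.build_transfer_operator(system)
pi = sf.stationary_distribution(operator)
flows = sf.information_flows(operator, pi, gammas=np.arange(6) / 10, tau_max=300)
print(sf.assign_roles(flows))
```

On the 10-node Krackhardt kite (degree-1 tail node 9 feeding through node 8
into a dense core around degree-6 hub node 3) this prints role scores

```
node 9  +0.969  initiator
node 8  +0.560  initiator
node 3  −1.000  stabilizer   (all core nodes score below −0.5)
```

i.e. the floppy tail injects the fluctuations and the hub carries the
attractor memory. The same pipeline exposes the supporting evidence:

* `free_energy_profile` — bistable, barrier F(0.5) − F(0) = 3.565 nats;
* `enumerate_tipping_trajectories` — 30,240 five-step paths from the
  all-zero state to the tipping level; `maximal_trajectories` finds the
  tied most-likely cascades, all starting from the tail
  (e.g. 9 → 8 → 7 → 5 → 6), the "domino effect";
* `commitment_probabilities` — at the tipping point, the hub's state
  predicts the future macrostate sign (P = 0.584) while node 8's predicts
  the opposite (P = 0.260);
* `intervention_experiment` / `pinning_role_ensemble` — Monte Carlo runs
  with one node clamped to 0: pinning the stabilizer collapses fluctuations
  (second-moment ratio 0.086 vs control) and suppresses transitions, while
  pinning the initiator does not.

The scripts in `examples/` run each of these end to end and print the
numbers above; the thin CLI does the same from a shell
(`spinflow all --graph kite --out results/`).

## Layout

- `src/spinflow/model.py` — Hamiltonian and Glauber flip rule
- `src/spinflow/dynamics.py` — exact transfer operator, stationary
  structure, level conditioning
- `src/spinflow/flows.py` — MI curves, μ, ω, role assignment
- `src/spinflow/paths.py` — tipping-trajectory enumeration and commitment
- `src/spinflow/interventions.py` — Monte Carlo simulator and pinning
  experiments
- `src/spinflow/graphs.py`, `pipeline.py`, `cli.py` — fixtures, I/O,
  end-to-end pipeline, CLI
- `docs/methods.md` — modelling assumptions, estimator choices, and
  limitations
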