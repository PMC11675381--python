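"""Most likely 5-step paths from the ground state to the tipping point.

Enumerates every 5-step single-flip trajectory of the kite system that
starts all-zero and ends with 5 of 10 nodes flipped, scores each by its
summed log transition probability, and prints the maximizers: the domino
cascades that start at the degree-1 tail tip and recruit progressively
better-connected nodes.  Also reports how committed each tipping-state node
is to the final attractor 10 steps later.
"""

import numpy as np

import spinflow as sf

system = sf.SpinSystem(graph=sf.make_kite(), beta=0.534)
operator = sf.build_transfer_operator(system)
start = operator.space.encode(np.zeros(10, dtype=int))

trajectories = sf.enumerate_tipping_trajectories(
    operator, operator.space, start, length=5, target_gamma=0.5
)
best = sf.maximal_trajectories(trajectories)
print(f"{len(trajectories)} trajectories reach the tipping level in 5 steps;")
print(f"{len(best)} tie at the maximal log-probability {best[0].objective:.4f}\n")

print("flip order of each maximizer (node flipped at steps 1..5):")
for traj in best:
    flips = [int(np.log2(a ^ b)) for a, b in zip(traj.states, traj.states[1:])]
    print("  ", " -> ".join(map(str, flips)))

print("\nMost cascades start at tail nodes 9/8 and move into the core —")
print("the domino effect: each flip destabilizes a better-connected node.")

for node in (3, 8):
    probs = sf.commitment_probabilities(operator, operator.space, node, horizon=10)
    print(
        f"node {node}: P(macrostate above 1/2 after 10 steps | node in state 1) "
        f"= {probs[1]['above']:.3f}"
    )
print("The hub (node 3) agrees with the future attractor sign; the gate")
print("node 8 anticorrelates — its flip is usually a failed excursion.")
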