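"""Causal pinning: promote or prevent transitions by freezing one node.

Computes roles on the kite, then runs Monte Carlo Glauber chains (100,000
update attempts, 8 seeds) with the top initiator (tail node 9) or the top
stabilizer (hub node 3) clamped to state 0, against an unpinned control.
Reported per arm: successful metastable transitions (strict side-to-side
crossings of the tipping level), macrostate fluctuation second moment and
time below tipping, both normalized by the control.
"""

import numpy as np

import spinflow as sf

system = sf.SpinSystem(graph=sf.make_kite(), beta=0.534)
operator = sf.build_transfer_operator(system)
pi = sf.stationary_distribution(operator)
flows = sf.information_flows(operator, pi, gammas=np.arange(0, 6) / 10, tau_max=300)
roles = sf.assign_roles(flows)

report = sf.intervention_experiment(
    system, roles, steps=100_000, seeds=range(8)
)
print("pinned nodes:", report.pinned_nodes)
cols = ["arm", "mean_transitions", "second_moment_ratio", "time_below_ratio"]
print(report.summary[cols].round(3).to_string(index=False))

print("\nPinning the initiator leaves transitions at or above the control;")
print("pinning the stabilizer suppresses them and traps the system on the")
print("pinned side (time below tipping goes up, fluctuations collapse).")
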