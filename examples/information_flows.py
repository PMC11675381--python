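"""Information-flow curves and initiator/stabilizer roles on the kite.

For every node and every distance-to-tipping level gamma, computes the
mutual information I(s_i^0 : S^t | <S^0> = gamma) between the node's state
and the whole system state t steps later, then summarizes each curve by

  mu    integrated mutual information (area above the node's long-run
        plateau): short-lived "working memory" the node injects;
  omega asymptotic information (plateau of the unconditioned curve):
        long-term memory about which attractor the system occupies.

The role score r = max-normalized mu minus max-normalized omega separates
initiators (r near +1, low degree, noise injectors) from stabilizers
(r near -1, high degree, attractor memory).
"""

import numpy as np

import spinflow as sf

system = sf.SpinSystem(graph=sf.make_kite(), beta=0.534)
operator = sf.build_transfer_operator(system)
pi = sf.stationary_distribution(operator)

# levels up to the tipping point; the zero-field model is flip-symmetric
flows = sf.information_flows(
    operator, pi, gammas=np.arange(0, 6) / 10, tau_max=300
)
roles = sf.assign_roles(flows)

print("node  degree     mu(g=0.1)   mu(g=0.5)    omega   role_score  label")
degrees = system.degrees()
for i, node in enumerate(flows.nodes):
    print(
        f"{node:4d}  {degrees[i]:6d}  {flows.mu[i, 1]:10.3f}  "
        f"{flows.mu[i, 5]:10.3f}  {flows.omega[i]:7.3f}  "
        f"{roles.loc[i, 'role_score']:10.3f}  {roles.loc[i, 'role_label']}"
    )

print("\nFar from tipping (gamma 0.1) the low-degree tail nodes 8 and 9 hold")
print("the largest integrated MI (they initiate fluctuations), while the")
print("high-degree core holds the largest omega (it remembers the attractor).")
print("Per-level omega rises towards the tipping point (early warning):")
print("  gamma:", ", ".join(f"{g:.1f}" for g in flows.gammas))
print("  mean omega:", ", ".join(f"{v:.4f}" for v in flows.omega_per_level.mean(axis=0)))
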