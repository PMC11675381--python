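"""Information-flow curves, integrated mutual information, and node roles.

For each node i and each magnetization level γ, the curve

    I_i,γ(t) = I(s_i^τ : S^{τ+t} | ⟨S^τ⟩ = γ)    [bits]

measures how much a node's present state tells about the entire system state
t steps later, given that the system currently sits at distance γ from the
tipping point.  The curve starts at the node's conditional entropy (≤ 1 bit)
and decays along the Markov chain (data-processing inequality); in a bistable
system it decays not to zero but to a plateau.

Two summary features decompose the curve:

* asymptotic information ω(s_i) — the sustained long-lag plateau of the MI
  curve, estimated as the mean over a tail window of lags.  By default it is
  taken from the *unconditioned* curve (time-0 ensemble = the full stationary
  distribution): there the plateau measures how much a node's state says
  about which attractor the system occupies, the long-term memory that core
  nodes carry and floppy low-degree nodes do not.  Conditioned per-level
  plateau estimates are also computed; their rise toward the tipping level is
  an early-warning signal.
* integrated mutual information μ(s_i|γ) = Σ_t (I(t) − ω)·Δt — the excess
  area of the conditional curve above the node's plateau; the intensity ×
  duration of the short-lived fluctuations the node injects ("working
  memory").

The role score r_i = max_γ μ*(i|γ) − max_γ ω*(i) ∈ [−1, 1] (stars denote
max-normalized variants) classifies nodes as initiators (r > 0, short-lived
noise propagators, typically low degree) or stabilizers (r < 0, long-term
memory carriers, typically high degree).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import (
    PartitionLevel,
    TransferOperator,
    conditional_state_distribution,
    stationary_distribution,
)

__all__ = [
    "MICurve",
    "InfoFlowResult",
    "DegenerateNormalizationError",
    "mi_curve",
    "estimate_omega",
    "integrated_mi",
    "information_flows",
    "assign_roles",
]


class DegenerateNormalizationError(ValueError):
    """Raised when every μ and ω vanishes, so no normalization exists."""


@dataclass(frozen=True)
class MICurve:
    """Mutual information I(s_i^0 : S^t | ⟨S^0⟩=γ) in bits, per lag t."""

    node: object
    gamma: float
    lags: np.ndarray
    values: np.ndarray


def _mi_bits(v1: np.ndarray, total: np.ndarray) -> float:
    """MI in bits from the sub-probability row for s_i=1 and the marginal."""
    v0 = total - v1
    # a constant node state (degenerate level) carries exactly zero information
    if v1.sum() <= 0.0 or v0.sum() <= 0.0:
        return 0.0
    out = 0.0
    for va in (v0, v1):
        pa = va.sum()
        mask = va > 0.0
        out += float(np.sum(va[mask] * np.log2(va[mask] / (pa * total[mask]))))
    return out


def _level_curves(
    t: TransferOperator, level: PartitionLevel, node_indices, tau_max: int
) -> np.ndarray:
    """MI curves for several nodes at one level, sharing the propagation.

    Propagates the level ensemble once per lag: row 0 carries the marginal
    state distribution, row 1+k the sub-probability mass where node k starts
    in state 1.  One (n+1) × 2^n by 2^n × 2^n product per lag.
    """
    start = level.full_vector(t.space)
    bits = t.space.states[:, node_indices].T            # (n_sel, 2^n)
    block = np.vstack([start[None, :], start[None, :] * bits])
    curves = np.empty((len(node_indices), tau_max + 1))
    for lag in range(tau_max + 1):
        if lag > 0:
            block = block @ t.matrix
        total = block[0]
        for k in range(len(node_indices)):
            curves[k, lag] = _mi_bits(block[1 + k], total)
    return curves


def mi_curve(
    t: TransferOperator, level: PartitionLevel, node, tau_max: int
) -> MICurve:
    """Information-flow curve of one node over lags 0..tau_max.

    Degenerate levels where the node state is constant (e.g. γ = 0) yield a
    curve of exact zeros.
    """
    if tau_max < 1:
        raise ValueError("tau_max must be >= 1")
    i = t.system.node_index(node)
    values = _level_curves(t, level, [i], tau_max)[0]
    return MICurve(
        node=node, gamma=level.gamma, lags=np.arange(tau_max + 1), values=values
    )


def _curve_values(curve) -> np.ndarray:
    return curve.values if isinstance(curve, MICurve) else np.asarray(curve, float)


def estimate_omega(curve, tail_fraction: float = 0.2) -> float:
    """Asymptotic information ω: mean of the curve over its final lags.

    The window covers the last ``tail_fraction`` of the lag range (the default
    0.2 at τ_max = 300 averages lags 241–300); the estimate is clipped below
    at zero since ω is a non-negative information quantity.
    """
    values = _curve_values(curve)
    if values.size < 10:
        raise ValueError("curve must have at least 10 lags to estimate omega")
    if not 0.0 < tail_fraction <= 0.5:
        raise ValueError("tail_fraction must lie in (0, 0.5]")
    window = max(1, int(round(tail_fraction * (values.size - 1))))
    return float(max(values[-window:].mean(), 0.0))


def integrated_mi(curve, omega: float) -> float:
    """Integrated mutual information μ = Σ_{t=0}^{τ_max} (I(t) − ω)·Δt, Δt = 1.

    The infinite-horizon sum is truncated at the curve's last lag.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    return float(_curve_values(curve).sum() - omega * _curve_values(curve).size)


@dataclass(frozen=True)
class InfoFlowResult:
    """Per-node, per-level information-flow summaries.

    ``omega_per_level`` always holds the tail estimate per (node, level);
    ``omega`` is what μ subtracts: one value per node for the
    ``"stationary"`` (unconditioned curve) and ``"shared"`` (largest tail
    across levels) modes, the per-level estimates themselves for
    ``"per-level"``.  ``stationary_curves`` holds the unconditioned MI
    curves when they were computed.
    """

    nodes: tuple
    gammas: np.ndarray
    curves: np.ndarray            # (n_nodes, n_levels, tau_max+1)
    mu: np.ndarray                # (n_nodes, n_levels), bits·steps
    omega: np.ndarray             # (n_nodes,) or (n_nodes, n_levels), bits
    omega_per_level: np.ndarray   # (n_nodes, n_levels), bits
    tau_max: int
    tail_fraction: float
    omega_mode: str
    stationary_curves: np.ndarray | None = None
    delta_t: float = 1.0

    @property
    def omega_by_node(self) -> np.ndarray:
        """One ω per node: the shared value, or the per-level maximum."""
        return self.omega if self.omega.ndim == 1 else self.omega.max(axis=1)

    @property
    def mu_star(self) -> np.ndarray:
        """μ clipped at zero and scaled by the global maximum, in [0, 1]."""
        top = self.mu.max()
        if top <= 0:
            return np.zeros_like(self.mu)
        return np.clip(self.mu, 0.0, None) / top

    @property
    def omega_star(self) -> np.ndarray:
        """ω per node scaled by the maximum over nodes, in [0, 1]."""
        omega = self.omega_by_node
        top = omega.max()
        return omega / top if top > 0 else np.zeros_like(omega)

    def curve(self, node, gamma: float) -> MICurve:
        i = self.nodes.index(node)
        g = int(np.argmin(np.abs(self.gammas - gamma)))
        if abs(self.gammas[g] - gamma) > 1e-9:
            raise KeyError(f"gamma={gamma} was not analyzed")
        return MICurve(
            node=node,
            gamma=float(self.gammas[g]),
            lags=np.arange(self.tau_max + 1),
            values=self.curves[i, g],
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy (node, gamma, lag, mi) frame of every curve."""
        n_nodes, n_levels, n_lags = self.curves.shape
        return pd.DataFrame(
            {
                "node": np.repeat(list(self.nodes), n_levels * n_lags),
                "gamma": np.tile(np.repeat(self.gammas, n_lags), n_nodes),
                "lag": np.tile(np.arange(n_lags), n_nodes * n_levels),
                "mi": self.curves.ravel(),
            }
        )


def information_flows(
    t: TransferOperator,
    pi: np.ndarray | None = None,
    gammas=None,
    tau_max: int = 300,
    tail_fraction: float = 0.2,
    omega_mode: str = "stationary",
) -> InfoFlowResult:
    """Compute MI curves, μ and ω for every node at the requested γ levels.

    Parameters
    ----------
    t
        Exact transfer operator.
    pi
        Stationary distribution; computed from ``t`` when omitted.  The
        time-0 ensemble at level γ is π restricted to that level.
    gammas
        Magnetization levels to condition on; defaults to every feasible
        level 0, 1/n, ..., 1.
    tau_max
        Lag horizon (default 300 steps); the curve has τ_max + 1 lags.
    tail_fraction
        Fraction of the lag range averaged to estimate ω (default 0.2).
    omega_mode
        ``"stationary"`` (default): one ω per node, the tail of the
        unconditioned MI curve (time-0 ensemble = π), subtracted at every
        level — the node's attractor memory.  ``"shared"``: one ω per node,
        the largest per-level tail estimate.  ``"per-level"``: each level
        subtracts its own tail estimate.
    """
    if omega_mode not in ("stationary", "shared", "per-level"):
        raise ValueError("omega_mode must be 'stationary', 'shared' or 'per-level'")
    if pi is None:
        pi = stationary_distribution(t)
    gammas = (
        t.space.gamma_levels() if gammas is None else np.sort(np.asarray(gammas, float))
    )
    nodes = t.system.nodes
    node_indices = list(range(len(nodes)))

    curves = np.empty((len(nodes), len(gammas), tau_max + 1))
    for g, gamma in enumerate(gammas):
        level = conditional_state_distribution(pi, t.space, gamma)
        curves[:, g, :] = _level_curves(t, level, node_indices, tau_max)

    omega_per_level = np.empty((len(nodes), len(gammas)))
    for i in range(len(nodes)):
        for g in range(len(gammas)):
            omega_per_level[i, g] = estimate_omega(curves[i, g], tail_fraction)

    stationary_curves = None
    if omega_mode == "stationary":
        full = PartitionLevel(
            gamma=np.nan,
            member_states=np.arange(t.space.size),
            conditional_dist=np.asarray(pi, float),
        )
        stationary_curves = _level_curves(t, full, node_indices, tau_max)
        omega = np.array(
            [estimate_omega(c, tail_fraction) for c in stationary_curves]
        )
        mu = curves.sum(axis=2) - omega[:, None] * (tau_max + 1)
    elif omega_mode == "shared":
        omega = omega_per_level.max(axis=1)
        mu = curves.sum(axis=2) - omega[:, None] * (tau_max + 1)
    else:
        omega = omega_per_level
        mu = curves.sum(axis=2) - omega * (tau_max + 1)

    return InfoFlowResult(
        nodes=nodes,
        gammas=gammas,
        curves=curves,
        mu=mu,
        omega=omega,
        omega_per_level=omega_per_level,
        tau_max=tau_max,
        tail_fraction=tail_fraction,
        omega_mode=omega_mode,
        stationary_curves=stationary_curves,
    )


def assign_roles(result: InfoFlowResult) -> pd.DataFrame:
    """Role score r_i = max_γ μ*(i|γ) − max_γ ω*(i) and label per node.

    Initiators (r > 0) dominate the short-lived information budget;
    stabilizers (r < 0) dominate the long-term memory.  The continuous score
    in [−1, 1] is always reported alongside the thresholded label.
    """
    if result.mu.max() <= 0 and result.omega_by_node.max() <= 0:
        raise DegenerateNormalizationError(
            "all mu and omega vanish; roles are undefined"
        )
    mu_best = result.mu_star.max(axis=1)
    omega_best = result.omega_star
    score = mu_best - omega_best
    label = np.where(score > 0, "initiator", np.where(score < 0, "stabilizer", "neutral"))
    return pd.DataFrame(
        {
            "node": list(result.nodes),
            "mu_star_max": mu_best,
            "omega_star_max": omega_best,
            "role_score": score,
            "role_label": label,
        }
    )
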