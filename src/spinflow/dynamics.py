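"""Exact single-step Markov dynamics on the full 2^n configuration space.

Builds the row-stochastic transfer operator for asynchronous Glauber updates
(one uniformly chosen node attempts a flip per time step), the stationary
distribution, the free-energy profile over the magnetization coordinate, and
the conditional ensembles obtained by restricting the stationary distribution
to a fixed magnetization level γ — the "distance to tipping point" partition.

State encoding is little-endian: node index i contributes bit i, so integer
index k encodes the configuration with s_i = (k >> i) & 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .model import SpinSystem

__all__ = [
    "CapacityError",
    "StateSpace",
    "TransferOperator",
    "PartitionLevel",
    "build_transfer_operator",
    "stationary_distribution",
    "free_energy_profile",
    "conditional_state_distribution",
    "evolve_joint",
]

#: default cap on n for exact enumeration (2^14 states ≈ 2 GiB dense operator)
DEFAULT_STATE_CAP = 14


class CapacityError(ValueError):
    """State space too large for exact enumeration."""


class StateSpace:
    """Bijection between integers 0..2^n−1 and binary spin configurations."""

    def __init__(self, n: int) -> None:
        if n < 1:
            raise ValueError("n must be >= 1")
        self.n = int(n)
        self.size = 1 << self.n
        # bit matrix: row k is the configuration encoded by integer k
        ks = np.arange(self.size, dtype=np.int64)
        self.states = ((ks[:, None] >> np.arange(self.n)) & 1).astype(np.int8)
        self.ones_count = self.states.sum(axis=1).astype(np.int64)

    def encode(self, states) -> int:
        arr = np.asarray(states, dtype=np.int64)
        if arr.size != self.n or not np.isin(arr, (0, 1)).all():
            raise ValueError(f"expected a binary vector of length {self.n}")
        return int((arr << np.arange(self.n)).sum())

    def decode(self, index: int) -> np.ndarray:
        if not 0 <= index < self.size:
            raise ValueError(f"state index {index} out of range [0, {self.size})")
        return self.states[index].copy()

    def magnetization(self, index: int) -> float:
        return self.ones_count[index] / self.n

    def gamma_levels(self) -> np.ndarray:
        """All feasible magnetization levels {0, 1/n, ..., 1}."""
        return np.arange(self.n + 1) / self.n

    def level_members(self, gamma: float) -> np.ndarray:
        """State indices with ⟨S⟩ = γ; raises if γ·n is not an integer."""
        k = gamma * self.n
        if abs(k - round(k)) > 1e-9:
            raise ValueError(f"gamma={gamma} is not a multiple of 1/{self.n}")
        k = int(round(k))
        if not 0 <= k <= self.n:
            raise ValueError(f"gamma={gamma} outside [0, 1]")
        return np.flatnonzero(self.ones_count == k)


@dataclass(frozen=True)
class TransferOperator:
    """Exact one-step transition matrix for single-flip Glauber dynamics.

    ``matrix[s, s']`` is the probability of moving from configuration ``s`` to
    ``s'`` in one step; off-diagonal mass sits only on Hamming-distance-1
    neighbours and carries the uniform 1/n node-selection factor.
    """

    matrix: np.ndarray
    space: StateSpace
    system: SpinSystem
    update_scheme: str = "single-flip-random-node"

    @property
    def n(self) -> int:
        return self.space.n


def build_transfer_operator(
    system: SpinSystem, cap: int = DEFAULT_STATE_CAP
) -> TransferOperator:
    """Construct the dense 2^n × 2^n transfer operator.

    Raises :class:`CapacityError` above ``cap`` nodes; for larger systems use
    the Monte Carlo simulator in :mod:`spinflow.interventions`.
    """
    n = system.n
    if n > cap:
        raise CapacityError(
            f"n={n} exceeds the exact-enumeration cap of {cap} "
            f"(2^{n} states); use the Monte Carlo simulator instead"
        )
    space = StateSpace(n)
    sigma = 2.0 * space.states - 1.0                    # (2^n, n)
    local_field = sigma @ system.adjacency()            # h_i per state
    delta_e = -2.0 * system.coupling * sigma * local_field
    p_flip = expit(system.beta * delta_e) / n           # T entry per (state, node)

    size = space.size
    t = np.zeros((size, size))
    rows = np.repeat(np.arange(size), n)
    cols = (np.arange(size)[:, None] ^ (1 << np.arange(n))[None, :]).ravel()
    t[rows, cols] = p_flip.ravel()
    t[np.arange(size), np.arange(size)] = 1.0 - p_flip.sum(axis=1)
    return TransferOperator(matrix=t, space=space, system=system)


def stationary_distribution(t: TransferOperator, tol: float = 1e-10) -> np.ndarray:
    """Stationary distribution π with πT = π, Σπ = 1.

    Solved directly as a linear system (replace one balance equation by the
    normalization constraint); the direct solve is robust even when
    bistability makes the spectral gap tiny.  Falls back to power iteration
    only if the direct solve fails to reach the residual tolerance.
    """
    m = t.matrix
    size = m.shape[0]
    a = m.T - np.eye(size)
    a[-1, :] = 1.0
    b = np.zeros(size)
    b[-1] = 1.0
    pi = np.linalg.solve(a, b)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    residual = np.abs(pi @ m - pi).sum()
    if residual >= tol:
        pi = _power_iteration(m, pi, tol)
        residual = np.abs(pi @ m - pi).sum()
        if residual >= tol:
            raise ArithmeticError(
                f"stationary solve did not converge: L1 residual {residual:.3e}"
            )
    return pi


def _power_iteration(m: np.ndarray, pi: np.ndarray, tol: float, max_iter: int = 10**6):
    for _ in range(max_iter):
        nxt = pi @ m
        nxt /= nxt.sum()
        if np.abs(nxt - pi).sum() < 0.1 * tol:
            return nxt
        pi = nxt
    return pi


def free_energy_profile(pi: np.ndarray, space: StateSpace) -> dict[float, float]:
    """Free energy −log Σ_{S:⟨S⟩=γ} π(S) per magnetization level γ.

    A bistable system shows two minima (the attractors near γ=0 and γ=1)
    separated by an interior barrier whose top is the tipping point γ=1/2.
    """
    pi = np.asarray(pi, dtype=float)
    if abs(pi.sum() - 1.0) > 1e-8 or (pi < -1e-12).any():
        raise ValueError("pi must be a normalized probability vector")
    profile: dict[float, float] = {}
    for k in range(space.n + 1):
        mass = pi[space.ones_count == k].sum()
        profile[k / space.n] = float(-np.log(mass)) if mass > 0 else np.inf
    return profile


@dataclass(frozen=True)
class PartitionLevel:
    """The stationary ensemble restricted to one magnetization level γ."""

    gamma: float
    member_states: np.ndarray          # state indices with ⟨S⟩ = γ
    conditional_dist: np.ndarray       # probabilities over member_states, sums to 1

    def full_vector(self, space: StateSpace) -> np.ndarray:
        """Conditional distribution embedded in the full 2^n state space."""
        v = np.zeros(space.size)
        v[self.member_states] = self.conditional_dist
        return v


def conditional_state_distribution(
    pi: np.ndarray, space: StateSpace, gamma: float
) -> PartitionLevel:
    """Restrict π to the level ⟨S⟩ = γ and renormalize."""
    members = space.level_members(gamma)
    weights = np.asarray(pi, dtype=float)[members]
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"level gamma={gamma} carries zero probability")
    return PartitionLevel(
        gamma=float(gamma), member_states=members, conditional_dist=weights / total
    )


def evolve_joint(
    t: TransferOperator, initial: PartitionLevel, node, lag: int
) -> np.ndarray:
    """Joint distribution p(s_i^0 = a, S^t = s' | ⟨S^0⟩ = γ).

    Returns a (2, 2^n) array whose row ``a`` is the sub-probability vector of
    future states reached from the part of the level ensemble where node i
    starts in state ``a``.  Rows sum to the marginals p(s_i^0 = a); the total
    mass is 1.
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    i = t.system.node_index(node)
    start = initial.full_vector(t.space)
    bit = t.space.states[:, i]
    joint = np.vstack([start * (bit == 0), start * (bit == 1)])
    for _ in range(lag):
        joint = joint @ t.matrix
    return joint
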