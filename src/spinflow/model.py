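"""Networked spin model with Boltzmann–Gibbs single-flip dynamics.

The model places a binary state :math:`s_i \\in \\{0, 1\\}` on every node of an
undirected graph.  Interactions follow the zero-field ferromagnetic Ising
Hamiltonian

.. math::

    E(S) = -J \\sum_{(i,j) \\in \\mathcal{E}} \\sigma_i \\sigma_j,
    \\qquad \\sigma_i = 2 s_i - 1,

and one node at a time attempts a flip with the Glauber acceptance probability

.. math::

    P(s_i \\to s_i') = \\frac{1}{1 + e^{-\\beta\\,\\Delta E}},

where :math:`\\Delta E = E_{\\mathrm{old}} - E_{\\mathrm{new}}` is the energy
released by the flip: energy-lowering flips are accepted with probability above
one half, and the inverse temperature :math:`\\beta \\ge 0` sets the noise level
(small β — noisy, nearly random flips; large β — nearly deterministic descent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import expit

__all__ = ["SpinSystem", "SpinConfiguration", "energy", "flip_probability"]


@dataclass(frozen=True)
class SpinSystem:
    """An undirected interaction graph with Glauber-dynamics parameters.

    Parameters
    ----------
    graph
        Connected, simple, undirected graph.  Node labels are arbitrary
        hashables; internally nodes are indexed ``0..n-1`` in sorted label
        order (see :attr:`nodes`).
    beta
        Inverse temperature β ≥ 0 (dimensionless noise parameter).
    coupling
        Ferromagnetic coupling constant J > 0 (dimensionless, default 1).
    """

    graph: nx.Graph
    beta: float
    coupling: float = 1.0
    nodes: tuple = field(init=False, repr=False)

    def __post_init__(self) -> None:
        g = self.graph
        if g.number_of_nodes() < 1:
            raise ValueError("graph must have at least one node")
        if g.is_directed() or g.is_multigraph():
            raise ValueError("graph must be simple and undirected")
        if nx.number_of_selfloops(g) > 0:
            raise ValueError("graph must not contain self-loops")
        if g.number_of_nodes() > 1 and not nx.is_connected(g):
            raise ValueError("graph must be connected")
        if not self.beta >= 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not self.coupling > 0:
            raise ValueError(f"coupling must be > 0, got {self.coupling}")
        object.__setattr__(self, "nodes", tuple(sorted(g.nodes())))

    @property
    def n(self) -> int:
        return len(self.nodes)

    def node_index(self, node) -> int:
        """Index of ``node`` in the canonical sorted order; KeyError if absent."""
        try:
            return self.nodes.index(node)
        except ValueError:
            raise KeyError(f"node {node!r} is not in the graph") from None

    def adjacency(self) -> np.ndarray:
        """Dense 0/1 adjacency matrix in canonical node order."""
        return nx.to_numpy_array(self.graph, nodelist=list(self.nodes), dtype=float)

    def degrees(self) -> np.ndarray:
        return np.array([self.graph.degree(v) for v in self.nodes], dtype=int)


class SpinConfiguration:
    """A length-n vector of binary node states with its magnetization ⟨S⟩."""

    __slots__ = ("states",)

    def __init__(self, states) -> None:
        arr = np.asarray(states)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("states must be 0 or 1")
        self.states = arr.astype(np.int8)

    def __len__(self) -> int:
        return self.states.size

    def __eq__(self, other) -> bool:
        return isinstance(other, SpinConfiguration) and np.array_equal(
            self.states, other.states
        )

    def __repr__(self) -> str:
        return f"SpinConfiguration({self.states.tolist()})"

    @property
    def magnetization(self) -> float:
        """Fraction of nodes in state 1, ⟨S⟩ ∈ [0, 1]."""
        return int(self.states.sum()) / self.states.size

    def spins(self) -> np.ndarray:
        """±1 spin variables σ = 2s − 1."""
        return (2 * self.states - 1).astype(float)

    def flipped(self, index: int) -> "SpinConfiguration":
        out = self.states.copy()
        out[index] ^= 1
        return SpinConfiguration(out)


def _as_states(system: SpinSystem, config) -> np.ndarray:
    states = config.states if isinstance(config, SpinConfiguration) else np.asarray(config)
    if states.size != system.n:
        raise ValueError(
            f"configuration has {states.size} entries for a {system.n}-node system"
        )
    return states.astype(np.int8)


def energy(system: SpinSystem, config) -> float:
    """Zero-field Ising energy E(S) = −J Σ_{(i,j)∈E} σ_i σ_j.

    All-aligned configurations attain the ground-state energy −J·m for a graph
    with m edges; each anti-aligned edge costs +2J relative to that.
    """
    states = _as_states(system, config)
    sigma = 2.0 * states - 1.0
    a = system.adjacency()
    return float(-0.5 * system.coupling * sigma @ a @ sigma)


def flip_probability(system: SpinSystem, config, node) -> float:
    """Glauber probability of flipping ``node`` from the given configuration.

    Uses ΔE = E(current) − E(flipped), so a flip that releases energy
    (ΔE > 0) is favoured.  For a zero local field (isolated node, or β = 0)
    the probability is exactly 1/2.
    """
    states = _as_states(system, config)
    i = system.node_index(node)
    sigma = 2.0 * states - 1.0
    local_field = sum(sigma[system.node_index(j)] for j in system.graph[node])
    delta_e = -2.0 * system.coupling * sigma[i] * local_field
    return float(expit(system.beta * delta_e))
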