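"""Trajectories from an attractor to the tipping point.

Enumerates all fixed-length single-flip state sequences from a start
configuration into a target magnetization level, scores each by its summed
log one-step transition probability (the full transfer-operator entry,
including the uniform 1/n node-selection factor), extracts the maximizers,
and computes attractor-commitment probabilities from the tipping ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import (
    StateSpace,
    TransferOperator,
    conditional_state_distribution,
    stationary_distribution,
)

__all__ = [
    "Trajectory",
    "enumerate_tipping_trajectories",
    "maximal_trajectories",
    "commitment_probabilities",
]


@dataclass(frozen=True)
class Trajectory:
    """An ordered state sequence with per-step log transition probabilities."""

    states: tuple
    step_logps: tuple
    objective: float

    def __len__(self) -> int:
        return len(self.states) - 1


def enumerate_tipping_trajectories(
    t: TransferOperator,
    space: StateSpace,
    start: int,
    length: int,
    target_gamma: float,
    allow_stays: bool = False,
) -> list[Trajectory]:
    """All length-``length`` trajectories from ``start`` into the γ level.

    Each step flips exactly one node (strictly positive transition
    probability); with ``allow_stays`` the chain may also remain in place,
    which only matters when ``length`` exceeds the number of flips needed.
    An unreachable target returns an empty list.

    From the all-zero state of an n-node graph into γ = k/n in exactly k
    steps every step must flip a distinct 0 node, so the count is the falling
    factorial n·(n−1)⋯(n−k+1) regardless of β.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    n = space.n
    target_ones = target_gamma * n
    if abs(target_ones - round(target_ones)) > 1e-9:
        raise ValueError(f"target gamma={target_gamma} is not a multiple of 1/{n}")
    target_ones = int(round(target_ones))

    logt = np.full_like(t.matrix, -np.inf)
    with np.errstate(divide="ignore"):
        np.log(t.matrix, out=logt, where=t.matrix > 0)

    flips = 1 << np.arange(n)
    out: list[Trajectory] = []
    path = [start]
    logps: list[float] = []

    def extend(state: int, steps_left: int, logp_sum: float) -> None:
        if steps_left == 0:
            if space.ones_count[state] == target_ones:
                out.append(
                    Trajectory(
                        states=tuple(path),
                        step_logps=tuple(logps),
                        objective=logp_sum,
                    )
                )
            return
        # prune: target must stay reachable in the remaining flips
        gap = abs(target_ones - space.ones_count[state])
        if gap > steps_left or (not allow_stays and (steps_left - gap) % 2 != 0):
            return
        successors = state ^ flips
        if allow_stays:
            successors = np.append(successors, state)
        for nxt in successors:
            lp = logt[state, nxt]
            if lp == -np.inf:
                continue
            path.append(int(nxt))
            logps.append(float(lp))
            extend(int(nxt), steps_left - 1, logp_sum + lp)
            path.pop()
            logps.pop()

    extend(start, length, 0.0)
    return out


def maximal_trajectories(
    trajectories: list[Trajectory], tie_tol: float = 1e-9
) -> list[Trajectory]:
    """The subset attaining the maximal objective, within ``tie_tol`` log units.

    Ties are exact up to round-off when maximizers are related by a graph
    automorphism; the result is sorted lexicographically on state indices.
    """
    if not trajectories:
        raise ValueError("trajectory collection is empty")
    best = max(traj.objective for traj in trajectories)
    winners = [traj for traj in trajectories if traj.objective >= best - tie_tol]
    return sorted(winners, key=lambda traj: traj.states)


def commitment_probabilities(
    t: TransferOperator, space: StateSpace, node, horizon: int = 10
) -> dict[int, dict[str, float]]:
    """Which attractor the system commits to, conditioned on a node's state.

    Starting from the stationary ensemble restricted to the tipping level
    ⟨S⟩ = 1/2 (requires even n), evolves ``horizon`` steps and reports, for
    each initial node state a ∈ {0, 1}, the conditional probabilities that the
    macrostate ends above, below, or exactly at the tipping level.

    A node whose ``above`` mass given a = 1 exceeds 1/2 "agrees" with the
    future macrostate sign; by global flip symmetry that mass equals the
    ``below`` mass given a = 0.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if space.n % 2 != 0:
        raise ValueError(f"tipping level is empty for odd n={space.n}")
    pi = stationary_distribution(t)
    level = conditional_state_distribution(pi, space, 0.5)

    i = t.system.node_index(node)
    start = level.full_vector(space)
    bit = space.states[:, i]
    joint = np.vstack([start * (bit == 0), start * (bit == 1)])
    for _ in range(horizon):
        joint = joint @ t.matrix

    half = space.n / 2
    above = space.ones_count > half
    below = space.ones_count < half
    tie = space.ones_count == half
    out: dict[int, dict[str, float]] = {}
    for a in (0, 1):
        mass = joint[a].sum()
        out[a] = {
            "above": float(joint[a][above].sum() / mass),
            "below": float(joint[a][below].sum() / mass),
            "tie": float(joint[a][tie].sum() / mass),
        }
    return out
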