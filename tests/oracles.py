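"""Independent brute-force oracles for tiny systems.

Everything here is written from first principles with explicit loops over
configurations and paths — no code shared with the package under test — so
it can serve as the ground truth for n <= 4 node graphs.

Configurations are dicts ``{node: 0/1}``; the integer encoding mirrors the
package's documented convention (node i in sorted label order contributes
bit i) so indices can be compared directly.
"""

import math
from itertools import product

import numpy as np


def all_configs(graph):
    nodes = sorted(graph.nodes())
    for bits in product((0, 1), repeat=len(nodes)):
        yield dict(zip(nodes, bits))


def config_index(graph, config):
    nodes = sorted(graph.nodes())
    return sum(config[v] << i for i, v in enumerate(nodes))


def oracle_energy(graph, config, coupling=1.0):
    total = 0.0
    for u, v in graph.edges():
        total += (2 * config[u] - 1) * (2 * config[v] - 1)
    return -coupling * total


def oracle_flip_probability(graph, beta, config, node, coupling=1.0):
    flipped = dict(config)
    flipped[node] = 1 - flipped[node]
    released = oracle_energy(graph, config, coupling) - oracle_energy(
        graph, flipped, coupling
    )
    return 1.0 / (1.0 + math.exp(-beta * released))


def oracle_transfer_matrix(graph, beta, coupling=1.0):
    nodes = sorted(graph.nodes())
    n = len(nodes)
    size = 2**n
    t = np.zeros((size, size))
    for config in all_configs(graph):
        s = config_index(graph, config)
        for node in nodes:
            flipped = dict(config)
            flipped[node] = 1 - flipped[node]
            p = oracle_flip_probability(graph, beta, config, node, coupling) / n
            t[s, config_index(graph, flipped)] = p
        t[s, s] = 1.0 - t[s].sum()
    return t


def oracle_boltzmann(graph, beta, coupling=1.0):
    size = 2 ** graph.number_of_nodes()
    weights = np.zeros(size)
    for config in all_configs(graph):
        weights[config_index(graph, config)] = math.exp(
            -beta * oracle_energy(graph, config, coupling)
        )
    return weights / weights.sum()


def oracle_level_weights(graph, beta, gamma, coupling=1.0):
    """Boltzmann distribution restricted to the level ⟨S⟩ = γ, renormalized."""
    n = graph.number_of_nodes()
    pi = oracle_boltzmann(graph, beta, coupling)
    weights = np.zeros_like(pi)
    for config in all_configs(graph):
        if sum(config.values()) == round(gamma * n):
            idx = config_index(graph, config)
            weights[idx] = pi[idx]
    return weights / weights.sum()


def oracle_joint_by_paths(graph, beta, gamma, node, lag, coupling=1.0):
    """Joint p(s_node^0 = a, S^lag = s') by explicit sum over all paths."""
    nodes = sorted(graph.nodes())
    node_pos = nodes.index(node)
    size = 2 ** len(nodes)
    t = oracle_transfer_matrix(graph, beta, coupling)
    start = oracle_level_weights(graph, beta, gamma, coupling)
    joint = np.zeros((2, size))
    for path in product(range(size), repeat=lag + 1):
        weight = start[path[0]]
        for a, b in zip(path, path[1:]):
            weight *= t[a, b]
        a0 = (path[0] >> node_pos) & 1
        joint[a0, path[-1]] += weight
    return joint


def oracle_mi_bits(joint):
    """I(A : B) in bits from a 2 x m joint probability table."""
    joint = np.asarray(joint, float)
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    mi = 0.0
    for a in range(joint.shape[0]):
        for b in range(joint.shape[1]):
            if joint[a, b] > 0:
                mi += joint[a, b] * math.log2(joint[a, b] / (pa[a] * pb[b]))
    return mi


def oracle_mi_curve(graph, beta, gamma, node, tau_max, coupling=1.0):
    """MI curve via oracle transfer-matrix powers (start = restricted Boltzmann)."""
    nodes = sorted(graph.nodes())
    node_pos = nodes.index(node)
    t = oracle_transfer_matrix(graph, beta, coupling)
    start = oracle_level_weights(graph, beta, gamma, coupling)
    size = start.size
    values = []
    for lag in range(tau_max + 1):
        step = np.linalg.matrix_power(t, lag)
        joint = np.zeros((2, size))
        for s in range(size):
            a = (s >> node_pos) & 1
            joint[a] += start[s] * step[s]
        values.append(oracle_mi_bits(joint))
    return np.array(values)
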