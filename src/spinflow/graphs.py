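"""Built-in graph fixtures and graph input/output.

The Krackhardt kite is the 10-node, 18-edge benchmark graph with a
one-degree tail (node 9) feeding through node 8 (degree 2) into an
increasingly connected core around hub node 3 (degree 6) — the degree
gradient that makes it the canonical worked example for domino-style
noise-induced transitions.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np

__all__ = ["make_kite", "make_er", "load_edge_list", "load_graphml", "load_graph"]


def make_kite() -> nx.Graph:
    """The Krackhardt kite with the standard labeling.

    Node 3 has degree 6 (hub), node 8 degree 2, node 9 degree 1 (tail tip);
    nodes 0..7 form the densely connected body.
    """
    return nx.krackhardt_kite_graph()


def make_er(
    n: int,
    p: float,
    seed: int,
    require_connected: bool = False,
    max_tries: int = 1000,
) -> nx.Graph:
    """A G(n, p) Erdős–Rényi sample, optionally rejection-sampled to be connected.

    Deterministic in ``seed``; retry seeds are derived from it.  Raises if no
    connected sample is found within ``max_tries`` draws (e.g. p = 0).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
        if not require_connected or n <= 1 or nx.is_connected(g):
            return g
    raise RuntimeError(
        f"no connected G({n}, {p}) sample found in {max_tries} draws"
    )


def load_edge_list(path) -> nx.Graph:
    """Read a two-column whitespace- or comma-separated edge list of node ids."""
    try:
        edges = np.loadtxt(path, dtype=np.int64, delimiter=None, comments="#", ndmin=2)
    except ValueError:
        # retry comma-separated
        edges = np.loadtxt(path, dtype=np.int64, delimiter=",", comments="#", ndmin=2)
    if edges.size and edges.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns of node ids")
    g = nx.Graph()
    g.add_edges_from(map(tuple, edges))
    return g


def load_graphml(path) -> nx.Graph:
    g = nx.read_graphml(path)
    # GraphML stores ids as strings; restore integer labels when possible
    try:
        return nx.relabel_nodes(g, {v: int(v) for v in g.nodes()})
    except (TypeError, ValueError):
        return g


def load_graph(source) -> nx.Graph:
    """Resolve a fixture name ('kite'), an edge-list path, or a GraphML path."""
    if source == "kite":
        return make_kite()
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"unknown graph source {source!r}")
    if path.suffix.lower() == ".graphml":
        return load_graphml(path)
    return load_edge_list(path)
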