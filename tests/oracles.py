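"""Independent reference implementations used to validate the package.

Everything here is deliberately naive — exhaustive enumeration or a
third-party library — and never shares code with the implementation it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from isoflow.graph_io import CostModel
from isoflow.offset_network import JunctionGraph


def brute_force_utejc(j: JunctionGraph, cm: CostModel, max_flow: int = 12) -> float:
    """Minimum deviation cost over ALL integer conservative flows on ``j``.

    Enumerates every assignment of 0..max_flow to every arc, keeps those
    satisfying conservation at internal nodes, and minimizes the summed
    cost.  Exponential — only for tiny instances.
    """
    edges = j.edges
    m = len(edges)
    internal = [v for v in j.nodes if v not in set(j.sources) | set(j.sinks)]
    A = np.zeros((len(internal), m), dtype=np.int64)
    for r, v in enumerate(internal):
        for c, (u, w) in enumerate(edges):
            if w == v:
                A[r, c] += 1
            if u == v:
                A[r, c] -= 1
    covs = np.array([j.edge_cov[e] for e in edges], dtype=np.int64)

    best = np.inf
    vals = np.arange(max_flow + 1, dtype=np.int64)
    # chunk over the first edge's value to bound memory
    rest = np.array(
        list(itertools.product(vals, repeat=m - 1)), dtype=np.int64
    ) if m > 1 else np.zeros((1, 0), dtype=np.int64)
    for v0 in vals:
        X = np.hstack([np.full((rest.shape[0], 1), v0, dtype=np.int64), rest])
        ok = np.all(A @ X.T == 0, axis=0) if len(internal) else np.ones(len(X), bool)
        if not ok.any():
            continue
        dev = np.abs(X[ok] - covs)
        if cm.family == "squared":
            costs = (dev.astype(float) ** 2).sum(axis=1)
        elif cm.family == "absolute":
            costs = dev.astype(float).sum(axis=1)
        else:
            w = np.where(covs > 0, 1.0 / np.sqrt(np.maximum(covs, 1)), 1.0)
            costs = (dev * w).sum(axis=1)
        best = min(best, costs.min())
    return float(best)


def brute_force_utec(g, cm: CostModel, max_expr: int = 6) -> float:
    """Minimum UTEC objective by enumerating per-path integer expressions.

    Enumerates every assignment of expression 0..max_expr to every
    source-to-sink path of ``g`` and evaluates the node+edge deviation
    cost directly.  Only for graphs with a handful of paths.
    """
    import networkx as nx

    nxg = g.to_networkx()
    paths = []
    for s in g.sources:
        for t in g.sinks:
            if s == t:
                paths.append((s,))
            else:
                paths.extend(tuple(p) for p in nx.all_simple_paths(nxg, s, t))
    best = np.inf
    for expr in itertools.product(range(max_expr + 1), repeat=len(paths)):
        node_flow = {v: 0 for v in g.nodes}
        edge_flow = {e: 0 for e in g.edges}
        for p, w in zip(paths, expr):
            for v in p:
                node_flow[v] += w
            for e in zip(p, p[1:]):
                edge_flow[e] += w
        cost = sum(
            cm.cost(abs(g.node_cov[v] - node_flow[v]), g.node_cov[v]) for v in g.nodes
        ) + sum(
            cm.cost(abs(g.edge_cov[e] - edge_flow[e]), g.edge_cov[e]) for e in g.edges
        )
        best = min(best, cost)
    return float(best)


def exhaustive_bottleneck(j: JunctionGraph, x: dict) -> int:
    """Max over all simple source-to-sink paths of the min arc flow."""
    import networkx as nx

    nxg = nx.DiGraph()
    nxg.add_nodes_from(j.nodes)
    nxg.add_edges_from(e for e, v in x.items() if v > 0)
    best = 0
    for s in j.sources:
        for t in j.sinks:
            if not nxg.has_node(s) or not nxg.has_node(t):
                continue
            for p in nx.all_simple_paths(nxg, s, t):
                best = max(best, min(x[e] for e in zip(p, p[1:])))
    return best


def reference_edit_distance(a: str, b: str) -> int:
    if not a or not b:
        return max(len(a), len(b))
    import edlib

    return edlib.align(a, b)["editDistance"]


def brute_force_matching_cost(cost: np.ndarray) -> int:
    """Minimum assignment cost by enumerating all permutations (n <= 6)."""
    n = cost.shape[0]
    return min(
        sum(cost[i, p[i]] for i in range(n))
        for p in itertools.permutations(range(n))
    )
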