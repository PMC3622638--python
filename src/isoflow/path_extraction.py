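"""Flow reconstruction and decomposition into weighted transcript paths.

From a canonical optimal offset flow ``x*`` the expression flow on the
junction graph is ``x_uv = cov(u, v) + x*_uv - x*_vu``.  This function is
a conservative flow: in-flow equals out-flow at every internal node and
total source out-flow equals total sink in-flow — both are asserted
exactly (integer arithmetic) on every run.

The flow is then decomposed into source-to-sink paths by repeatedly
extracting the *heaviest* path — the path maximizing its minimum arc flow
(maximum-bottleneck path, dynamic programming over a topological order) —
and subtracting its bottleneck from the flow until nothing remains.  Each
extraction zeroes at least one arc, so at most ``|E|`` paths are emitted
and their weights are non-increasing.  Finding a decomposition with the
fewest paths is NP-hard; this greedy policy is the pragmatic standard.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .graph_io import CostModel
from .mincost_solver import Flow
from .offset_network import Edge, JunctionGraph, Node

__all__ = [
    "TranscriptPath",
    "reconstruct_flow",
    "check_conservation",
    "heaviest_path",
    "decompose",
    "superpose",
    "utejc_objective",
]


@dataclass(frozen=True)
class TranscriptPath:
    """A predicted transcript: exon sequence plus expression weight."""

    nodes: tuple[str, ...]
    expression: int

    def __post_init__(self) -> None:
        if self.expression <= 0:
            raise ValueError("transcript expression must be positive")


def reconstruct_flow(x_star: Flow, j: JunctionGraph) -> dict[Edge, int]:
    """Map a canonical offset flow back to expression flow on ``j``."""
    pairs = x_star.network.arc_pairs()
    x: dict[Edge, int] = {}
    for e in j.edges:
        fwd, rev = pairs[e]
        val = int(j.edge_cov[e]) + x_star.values[fwd] - x_star.values[rev]
        if val < 0:
            raise AssertionError(f"negative reconstructed flow on {e}")
        x[e] = val
    check_conservation(j, x)
    return x


def check_conservation(j: JunctionGraph, x: dict[Edge, int]) -> tuple[int, int]:
    """Assert exact flow conservation; return (source out-flow, sink in-flow)."""
    inflow: dict[Node, int] = {v: 0 for v in j.nodes}
    outflow: dict[Node, int] = {v: 0 for v in j.nodes}
    for (u, v), val in x.items():
        outflow[u] += val
        inflow[v] += val
    endpoints = set(j.sources) | set(j.sinks)
    for v in j.nodes:
        if v in endpoints:
            continue
        if inflow[v] != outflow[v]:
            raise AssertionError(
                f"conservation violated at {v}: in {inflow[v]} != out {outflow[v]}")
    src_out = sum(outflow[s] for s in j.sources)
    sink_in = sum(inflow[t] for t in j.sinks)
    if src_out != sink_in:
        raise AssertionError(f"source/sink imbalance: {src_out} != {sink_in}")
    return src_out, sink_in


def _topo_order(j: JunctionGraph) -> list[Node]:
    g = nx.DiGraph()
    g.add_nodes_from(j.nodes)
    g.add_edges_from(j.edges)
    return list(nx.topological_sort(g))


def heaviest_path(
    j: JunctionGraph, x: dict[Edge, int], order: list[Node] | None = None
) -> tuple[list[Node], int]:
    """Maximum-bottleneck source-to-sink path through positive-flow arcs.

    Ties are broken toward the predecessor (and sink) earliest in the
    topological order, making the result deterministic.  Raises
    ``ValueError`` when no positive-flow path exists.
    """
    order = order if order is not None else _topo_order(j)
    INF = float("inf")
    rank = {v: i for i, v in enumerate(order)}
    best: dict[Node, float] = {}
    pred: dict[Node, Node] = {}
    in_arcs: dict[Node, list[tuple[Node, int]]] = {v: [] for v in j.nodes}
    for (u, v), val in x.items():
        if val > 0:
            in_arcs[v].append((u, val))
    sources = set(j.sources)
    for v in order:
        if v in sources:
            best[v] = INF  # sources have in-degree 0; any path has >= 1 arc
            continue
        for u, val in sorted(in_arcs[v], key=lambda t: rank[t[0]]):
            if u not in best:
                continue
            cand = min(best[u], val)
            if cand > best.get(v, 0):  # strict: ties keep the earlier predecessor
                best[v] = cand
                pred[v] = u
    best_sink: Node | None = None
    best_val = 0
    for t in sorted(j.sinks, key=lambda n: rank[n]):
        val = best.get(t)
        if val is None or val == INF or val <= 0:
            continue
        if val > best_val:
            best_val = val
            best_sink = t
    if best_sink is None:
        raise ValueError("no source-to-sink path with positive flow")
    path = [best_sink]
    while path[-1] in pred:
        path.append(pred[path[-1]])
    path.reverse()
    return path, int(best_val)


def _merge_origin(j: JunctionGraph, path: list[Node]) -> tuple[str, ...]:
    """Collapse v_in/v_out pairs back to original exon identifiers."""
    if not j.origin_node:
        return tuple(path)
    merged: list[str] = []
    for n in path:
        orig, _half = j.origin_node[n]
        if not merged or merged[-1] != orig:
            merged.append(orig)
    return tuple(merged)


def decompose(j: JunctionGraph, x: dict[Edge, int]) -> list[TranscriptPath]:
    """Greedy heaviest-path flow decomposition.

    Returns transcript paths (original exon identifiers when the instance
    came from node splitting) with positive, non-increasing weights whose
    superposition reproduces ``x`` arc-exactly.
    """
    residual = dict(x)
    order = _topo_order(j)
    out: list[TranscriptPath] = []
    max_iter = len(j.edges)
    while any(v > 0 for v in residual.values()):
        if len(out) >= max_iter:
            raise AssertionError("decomposition did not terminate in |E| steps")
        path, w = heaviest_path(j, residual, order)
        for e in zip(path, path[1:]):
            residual[e] -= w
            if residual[e] < 0:
                raise AssertionError(f"residual flow went negative on {e}")
        out.append(TranscriptPath(_merge_origin(j, path), w))
    return out


def _junction_edges_of(j: JunctionGraph, p: TranscriptPath) -> list[Edge]:
    """Junction arcs traversed by a transcript path."""
    if not j.origin_node:
        return list(zip(p.nodes, p.nodes[1:]))
    edges: list[Edge] = []
    for v in p.nodes:
        edges.append(((v, "in"), (v, "out")))
    for u, v in zip(p.nodes, p.nodes[1:]):
        edges.append(((u, "out"), (v, "in")))
    return edges


def superpose(j: JunctionGraph, paths: list[TranscriptPath]) -> dict[Edge, int]:
    """Arc-wise sum of path expressions: the flow the paths induce on ``j``."""
    x = {e: 0 for e in j.edges}
    for p in paths:
        for e in _junction_edges_of(j, p):
            x[e] += p.expression
    return x


def utejc_objective(
    j: JunctionGraph,
    paths_or_flow: list[TranscriptPath] | dict[Edge, int],
    cm: CostModel | None = None,
) -> float:
    """Sum of per-arc deviation costs between coverage and explained flow."""
    cm = cm or CostModel("squared")
    x = (
        paths_or_flow
        if isinstance(paths_or_flow, dict)
        else superpose(j, paths_or_flow)
    )
    total = 0.0
    for e in j.edges:
        cov = int(j.edge_cov[e])
        fam = j.edge_family.get(e) or cm.family
        total += CostModel(fam).cost(abs(cov - x.get(e, 0)), cov)
    return total
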