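"""Node splitting and offset-network construction.

Two transformations live here.

``split_nodes`` turns a node-and-edge-covered splicing graph into an
equivalent *junction graph* carrying coverage only on arcs: every node
``v`` becomes ``v_in -> v_out`` with the node's coverage and cost family
on that arc, and every original edge ``(u, v)`` becomes ``(u_out, v_in)``.
Optimal weighted path sets correspond one-to-one between the two
instances, with equal objective.

``build_offset_network`` builds the auxiliary flow network whose min-cost
flow encodes, per junction arc, the signed deviation (offset) between the
observed coverage and the fitted expression flow:

* each junction arc ``(u, v)`` gets a forward offset arc (unbounded, cost
  ``f_uv``) and a reverse arc ``(v, u)`` capped at ``cov(u, v)`` with the
  same cost — positive and negative offsets respectively;
* per-node coverage imbalance (out-coverage minus in-coverage) is routed
  to special nodes ``t*`` (surplus) / from ``s*`` (deficit) through
  zero-cost arcs saturated in every feasible flow, with the matching
  exogenous flow booked on ``t*``/``s*``;
* auxiliary circulation arcs ``s0 -> sources``, ``sinks -> t0`` and
  ``t0 -> s0`` (unbounded, zero cost) let fitted expression circulate.

By construction the exogenous flows sum to zero, which is asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

from .graph_io import CostModel, SplicingGraph

__all__ = [
    "JunctionGraph",
    "Arc",
    "OffsetNetwork",
    "split_nodes",
    "build_offset_network",
    "S0",
    "T0",
    "S_STAR",
    "T_STAR",
]

Node = Hashable
Edge = tuple[Node, Node]

# special offset-network nodes; tuples cannot collide with ('v', 'in'/'out')
S0 = ("*aux*", "s0")
T0 = ("*aux*", "t0")
S_STAR = ("*aux*", "s*")
T_STAR = ("*aux*", "t*")


@dataclass
class JunctionGraph:
    """Splicing DAG with coverages (and cost families) on arcs only."""

    nodes: list[Node] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)
    edge_cov: dict[Edge, int] = field(default_factory=dict)
    edge_family: dict[Edge, str | None] = field(default_factory=dict)
    sources: tuple[Node, ...] = ()
    sinks: tuple[Node, ...] = ()
    # provenance of split instances; empty when the instance is native
    origin_node: dict[Node, tuple[str, str]] = field(default_factory=dict)
    origin_edge: dict[Edge, tuple[str, object]] = field(default_factory=dict)

    def out_cov(self, v: Node) -> int:
        return sum(c for (u, w), c in self.edge_cov.items() if u == v)

    def in_cov(self, v: Node) -> int:
        return sum(c for (u, w), c in self.edge_cov.items() if w == v)

    def total_coverage(self) -> int:
        return sum(self.edge_cov.values())


def split_nodes(g: SplicingGraph) -> JunctionGraph:
    """Reduce a node+edge covered instance to an arc-covered one.

    Each node ``v`` is replaced by the exon arc ``(v_in, v_out)`` carrying
    ``cov(v)`` and the node cost family; each edge ``(u, v)`` by the
    junction arc ``(u_out, v_in)``.  Sources map to their ``_in`` half,
    sinks to their ``_out`` half.
    """
    j = JunctionGraph()
    for v in g.nodes:
        vin, vout = (v, "in"), (v, "out")
        j.nodes.extend([vin, vout])
        j.origin_node[vin] = (v, "in")
        j.origin_node[vout] = (v, "out")
        arc = (vin, vout)
        j.edges.append(arc)
        j.edge_cov[arc] = g.node_cov[v]
        j.edge_family[arc] = g.node_cost_id
        j.origin_edge[arc] = ("exon", v)
    for u, v in g.edges:
        arc = ((u, "out"), (v, "in"))
        j.edges.append(arc)
        j.edge_cov[arc] = g.edge_cov[(u, v)]
        j.edge_family[arc] = g.edge_cost_id
        j.origin_edge[arc] = ("junction", (u, v))
    j.sources = tuple((s, "in") for s in g.sources)
    j.sinks = tuple((t, "out") for t in g.sinks)
    return j


@dataclass(frozen=True)
class Arc:
    """One arc of the offset network.

    ``model`` is ``None`` for zero-cost arcs; otherwise the convex cost is
    ``model.cost(x, cov)``.  ``edge`` back-references the junction arc the
    offset applies to (``None`` for auxiliary/imbalance arcs).  ``kind`` is
    one of ``offset_fwd``, ``offset_rev``, ``aux``, ``imbalance``.
    """

    u: Node
    v: Node
    cap: int
    model: CostModel | None
    cov: int
    kind: str
    edge: Edge | None = None

    def cost(self, x: int) -> float:
        return 0.0 if self.model is None else self.model.cost(x, self.cov)

    def marginal(self, i: int) -> float:
        return 0.0 if self.model is None else self.model.marginal(i, self.cov)

    def is_linear(self) -> bool:
        return self.model is None or self.model.is_linear(self.cov)


@dataclass
class OffsetNetwork:
    nodes: list[Node]
    arcs: list[Arc]
    q: dict[Node, int]
    junction: JunctionGraph
    big: int  # materialized "infinite" capacity

    def arc_pairs(self) -> dict[Edge, tuple[int, int]]:
        """Map junction edge -> (forward arc index, reverse arc index)."""
        fwd: dict[Edge, int] = {}
        rev: dict[Edge, int] = {}
        for i, a in enumerate(self.arcs):
            if a.kind == "offset_fwd":
                fwd[a.edge] = i
            elif a.kind == "offset_rev":
                rev[a.edge] = i
        return {e: (fwd[e], rev[e]) for e in fwd}

    def to_dot(self) -> str:
        """Debug dump in DOT format."""
        lines = ["digraph offset_network {"]
        names = {n: f"n{i}" for i, n in enumerate(self.nodes)}
        for n in self.nodes:
            qv = self.q.get(n, 0)
            label = "/".join(str(p) for p in n) if isinstance(n, tuple) else str(n)
            extra = f"\\nq={qv}" if qv else ""
            lines.append(f'  {names[n]} [label="{label}{extra}"];')
        for a in self.arcs:
            fam = a.model.family if a.model else "0"
            lines.append(
                f'  {names[a.u]} -> {names[a.v]} '
                f'[label="b={a.cap} c={fam}" style={"solid" if a.kind.startswith("offset") else "dashed"}];'
            )
        lines.append("}")
        return "\n".join(lines)


def build_offset_network(j: JunctionGraph, cm: CostModel | None = None) -> OffsetNetwork:
    """Construct the offset network for a junction graph.

    ``cm`` supplies the cost family for arcs whose instance left it
    unspecified.  Coverages must already be integers.
    """
    cm = cm or CostModel("squared")
    for e, c in j.edge_cov.items():
        if int(c) != c:
            raise ValueError(f"non-integer coverage on {e}; discretize first")

    big = int(j.total_coverage()) + 1
    nodes = list(j.nodes) + [S0, T0, S_STAR, T_STAR]
    q: dict[Node, int] = {n: 0 for n in nodes}
    arcs: list[Arc] = []

    for e in j.edges:
        u, v = e
        cov = int(j.edge_cov[e])
        fam = j.edge_family.get(e) or cm.family
        model = CostModel(fam)
        arcs.append(Arc(u, v, big, model, cov, "offset_fwd", e))
        arcs.append(Arc(v, u, cov, model, cov, "offset_rev", e))

    for s in j.sources:
        arcs.append(Arc(S0, s, big, None, 0, "aux"))
    for t in j.sinks:
        arcs.append(Arc(t, T0, big, None, 0, "aux"))
    arcs.append(Arc(T0, S0, big, None, 0, "aux"))

    for v in j.nodes:
        surplus = j.out_cov(v) - j.in_cov(v)
        if surplus > 0:
            arcs.append(Arc(v, T_STAR, surplus, None, 0, "imbalance"))
            q[T_STAR] -= surplus
        elif surplus < 0:
            arcs.append(Arc(S_STAR, v, -surplus, None, 0, "imbalance"))
            q[S_STAR] += -surplus

    assert sum(q.values()) == 0, "exogenous flows must balance (construction bug)"
    return OffsetNetwork(nodes=nodes, arcs=arcs, q=q, junction=j, big=big)
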