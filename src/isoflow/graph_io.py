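"""Splicing-graph data model, validation, and TSV input/output.

A splicing graph summarizes the spliced read alignments of one gene: nodes
are exon segments (maximal stretches of the genome uninterrupted by any
splice junction), directed edges are observed junctions between segments,
and both carry an observed coverage (reads per position for a node, split
reads for an edge).  Transcripts are source-to-sink paths; identification
and quantification means finding a small set of weighted paths whose
superposition explains the observed coverages under a convex deviation
cost.

File dialect (one or more genes per file)::

    #graph <gene_id>
    N <node_id> <coverage>
    E <from_id> <to_id> <coverage>
    S <node_id>          # designated transcript start
    T <node_id>          # designated transcript end

Lines starting with ``#`` (other than ``#graph``) are comments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, TextIO

import networkx as nx

__all__ = [
    "COST_FAMILIES",
    "CostModel",
    "SplicingGraph",
    "GraphParseError",
    "GraphValidationError",
    "load_graph",
    "load_graphs",
    "write_graph",
    "write_graphs",
    "scale_to_integer",
]

COST_FAMILIES = ("squared", "absolute", "sqrt_normalized")


class GraphParseError(ValueError):
    """Malformed graph file (bad record, unknown node reference, ...)."""


class GraphValidationError(ValueError):
    """Structurally invalid splicing graph (cycle, orphan node, ...)."""


@dataclass(frozen=True)
class CostModel:
    """Convex deviation cost family for coverage offsets.

    ``cost(x, cov)`` is the penalty for explaining an element of observed
    coverage ``cov`` with a flow differing from it by ``x >= 0`` units.

    Families
    --------
    squared
        ``f(x) = x**2`` — least sum of squares.
    absolute
        ``f(x) = x`` — least sum of absolute differences.
    sqrt_normalized
        ``f(x) = x / sqrt(cov)`` — deviations weighted down on
        well-covered elements; falls back to ``f(x) = x`` when the
        observed coverage is zero (the normalization is undefined there).
    """

    family: str = "squared"

    def __post_init__(self) -> None:
        if self.family not in COST_FAMILIES:
            raise ValueError(f"unknown cost family {self.family!r}; "
                             f"expected one of {COST_FAMILIES}")

    def cost(self, x: float, cov: float) -> float:
        x = abs(x)
        if self.family == "squared":
            return x * x
        if self.family == "absolute":
            return x
        return x / math.sqrt(cov) if cov > 0 else float(x)

    def marginal(self, i: int, cov: float) -> float:
        """Incremental cost ``f(i) - f(i - 1)`` of the i-th offset unit."""
        if i < 1:
            raise ValueError("marginal index must be >= 1")
        if self.family == "squared":
            return 2 * i - 1
        if self.family == "absolute":
            return 1
        return 1.0 / math.sqrt(cov) if cov > 0 else 1.0

    def is_linear(self, cov: float) -> bool:
        """True when the marginal cost does not depend on the offset."""
        return self.family != "squared"


@dataclass
class SplicingGraph:
    """A validated per-gene splicing DAG with coverages.

    Attributes
    ----------
    nodes : list of node identifiers (opaque strings), in file/creation order.
    edges : list of ``(u, v)`` pairs.
    node_cov, edge_cov : nonnegative coverage per node / edge.
    sources, sinks : designated transcript start / end nodes.
    node_cost_id, edge_cost_id : optional cost-family identifiers attached
        to the instance; ``None`` defers the choice to solve time.
    """

    gene_id: str = "gene"
    nodes: list[str] = field(default_factory=list)
    edges: list[tuple[str, str]] = field(default_factory=list)
    node_cov: dict[str, float] = field(default_factory=dict)
    edge_cov: dict[tuple[str, str], float] = field(default_factory=dict)
    sources: tuple[str, ...] = ()
    sinks: tuple[str, ...] = ()
    node_cost_id: str | None = None
    edge_cost_id: str | None = None

    # -- structure helpers -------------------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def copy(self) -> "SplicingGraph":
        return replace(
            self,
            nodes=list(self.nodes),
            edges=list(self.edges),
            node_cov=dict(self.node_cov),
            edge_cov=dict(self.edge_cov),
        )

    # -- validation --------------------------------------------------------

    def validate(self) -> "SplicingGraph":
        """Check all structural invariants; return self or raise."""
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise GraphValidationError("duplicate node identifier")
        for u, v in self.edges:
            if u not in node_set or v not in node_set:
                raise GraphParseError(f"edge ({u},{v}) references undeclared node")
        for v, c in self.node_cov.items():
            if c < 0:
                raise GraphValidationError(f"negative coverage on node {v}")
        for e, c in self.edge_cov.items():
            if c < 0:
                raise GraphValidationError(f"negative coverage on edge {e}")
        if not self.sources or not self.sinks:
            raise GraphValidationError("graph must declare >=1 source and >=1 sink")

        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise GraphValidationError("cycle in splicing graph")
        for s in self.sources:
            if s not in node_set:
                raise GraphParseError(f"undeclared source {s}")
            if g.in_degree(s) != 0:
                raise GraphValidationError(f"source {s} has incoming edges")
        for t in self.sinks:
            if t not in node_set:
                raise GraphParseError(f"undeclared sink {t}")
            if g.out_degree(t) != 0:
                raise GraphValidationError(f"sink {t} has outgoing edges")

        # every node must lie on some source-to-sink path
        fwd = set(self.sources)
        for s in self.sources:
            fwd |= nx.descendants(g, s)
        bwd = set(self.sinks)
        rev = g.reverse(copy=False)
        for t in self.sinks:
            bwd |= nx.descendants(rev, t)
        stranded = node_set - (fwd & bwd)
        if stranded:
            raise GraphValidationError(
                f"orphan node(s) not on any source-to-sink path: {sorted(stranded)}")
        return self


# ---------------------------------------------------------------------------
# parsing / writing


def _parse_blocks(lines: Iterable[str], origin: str) -> list[SplicingGraph]:
    graphs: list[SplicingGraph] = []
    cur: SplicingGraph | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#graph"):
            parts = line.split()
            gene = parts[1] if len(parts) > 1 else f"gene{len(graphs) + 1}"
            cur = SplicingGraph(gene_id=gene)
            graphs.append(cur)
            continue
        if line.startswith("#"):
            continue
        if cur is None:  # tolerate files without the header line
            cur = SplicingGraph()
            graphs.append(cur)
        parts = line.split("\t") if "\t" in line else line.split()
        kind = parts[0]
        try:
            if kind == "N":
                _, nid, cov = parts
                if nid in cur.node_cov:
                    raise GraphParseError(f"{origin}:{lineno}: duplicate node {nid}")
                cur.nodes.append(nid)
                cur.node_cov[nid] = float(cov)
            elif kind == "E":
                _, u, v, cov = parts
                if u not in cur.node_cov or v not in cur.node_cov:
                    raise GraphParseError(
                        f"{origin}:{lineno}: edge references undeclared node")
                if (u, v) in cur.edge_cov:
                    raise GraphParseError(f"{origin}:{lineno}: duplicate edge ({u},{v})")
                cur.edges.append((u, v))
                cur.edge_cov[(u, v)] = float(cov)
            elif kind == "S":
                cur.sources = cur.sources + (parts[1],)
            elif kind == "T":
                cur.sinks = cur.sinks + (parts[1],)
            else:
                raise GraphParseError(f"{origin}:{lineno}: unknown record type {kind!r}")
        except (ValueError, IndexError) as exc:
            if isinstance(exc, (GraphParseError, GraphValidationError)):
                raise
            raise GraphParseError(f"{origin}:{lineno}: malformed line {line!r}") from exc
    return graphs


def load_graphs(path: str | Path) -> list[SplicingGraph]:
    """Read every ``#graph`` block in ``path``; validate each."""
    path = Path(path)
    with path.open() as fh:
        graphs = _parse_blocks(fh, str(path))
    if not graphs:
        raise GraphParseError(f"{path}: no graph records found")
    for g in graphs:
        g.validate()
    return graphs


def load_graph(path: str | Path) -> SplicingGraph:
    """Read a single-gene graph file (the first block if several)."""
    return load_graphs(path)[0]


def _fmt(c: float) -> str:
    return repr(int(c)) if float(c).is_integer() else repr(float(c))


def write_graph(g: SplicingGraph, out: TextIO | str | Path) -> None:
    if not hasattr(out, "write"):
        with Path(out).open("w") as fh:
            write_graph(g, fh)
        return
    out.write(f"#graph {g.gene_id}\n")
    for v in g.nodes:
        out.write(f"N\t{v}\t{_fmt(g.node_cov[v])}\n")
    for u, v in g.edges:
        out.write(f"E\t{u}\t{v}\t{_fmt(g.edge_cov[(u, v)])}\n")
    for s in g.sources:
        out.write(f"S\t{s}\n")
    for t in g.sinks:
        out.write(f"T\t{t}\n")


def write_graphs(graphs: Iterable[SplicingGraph], out: TextIO | str | Path) -> None:
    if not hasattr(out, "write"):
        with Path(out).open("w") as fh:
            write_graphs(graphs, fh)
        return
    for g in graphs:
        write_graph(g, out)


# ---------------------------------------------------------------------------


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def scale_to_integer(g: SplicingGraph, scale: float = 1.0) -> SplicingGraph:
    """Return a copy with every coverage replaced by round(cov * scale).

    The flow engine is exact only on integers; coverages (reads per
    position) are generally fractional, so they are discretized here.
    Rounding is half away from zero.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    out = g.copy()
    out.node_cov = {v: _round_half_away(c * scale) for v, c in g.node_cov.items()}
    out.edge_cov = {e: _round_half_away(c * scale) for e, c in g.edge_cov.items()}
    return out
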