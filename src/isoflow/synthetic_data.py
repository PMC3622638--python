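"""Random splicing-graph instances with known ground-truth transcripts.

The generator emulates, at graph level, the conditions of a simulated
RNA-Seq study: a random exon DAG, a handful of transcripts sampled as
random source-to-sink walks, expression levels drawn from a lognormal
distribution whose underlying normal has mean -4 and variance 1 (the
standard read-simulator convention), and coverages set to the exact
superposition of the truth paths.  Raw lognormal draws are far below 1,
so they are scaled (default 1e6, mirroring per-million normalizations)
and rounded to positive integers before use.

Optional noise models perturb coverages directly — multiplicative
Gaussian (``cov * max(0, 1 + sigma * Z)``) or Poisson resampling with the
coverage as mean — leaving the ground truth untouched.  Read-level
artifacts (positional bias, sequencing errors, fragment-length effects)
are deliberately not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .graph_io import SplicingGraph
from .path_extraction import TranscriptPath

__all__ = [
    "NoiseSpec",
    "SyntheticInstance",
    "generate_dag",
    "sample_truth",
    "perturb",
    "attach_sequences",
    "parallel_chains_instance",
    "draw_expressions",
]

LOGNORMAL_MEAN = -4.0
LOGNORMAL_SIGMA = 1.0
DEFAULT_EXPRESSION_SCALE = 1e6


@dataclass(frozen=True)
class NoiseSpec:
    """Coverage noise model: ``none``, ``mgauss`` (sigma) or ``poisson``."""

    kind: str = "none"
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "mgauss", "poisson"):
            raise ValueError(f"unknown noise kind {self.kind!r}")

    @classmethod
    def parse(cls, text: str) -> "NoiseSpec":
        """Parse ``none``, ``poisson`` or ``mgauss:<sigma>``."""
        if text == "none" or text == "poisson":
            return cls(text)
        if text.startswith("mgauss:"):
            return cls("mgauss", float(text.split(":", 1)[1]))
        raise ValueError(f"cannot parse noise spec {text!r}")


@dataclass
class SyntheticInstance:
    graph: SplicingGraph
    truth_paths: list[TranscriptPath]
    seed: int
    noise: NoiseSpec = NoiseSpec()
    sequences: dict[str, str] = field(default_factory=dict)  # exon -> nucleotides


def generate_dag(
    n_nodes: int, edge_density: float = 0.3, seed: int = 0
) -> SplicingGraph:
    """Random splicing-DAG skeleton (all coverages zero), deterministic per seed.

    Nodes are placed in a random topological order and each forward pair
    becomes an edge with probability ``edge_density``.  All in-degree-0
    nodes are sources and all out-degree-0 nodes sinks, so every node lies
    on a source-to-sink path by construction.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not 0 < edge_density <= 1:
        raise ValueError("edge_density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    order = [f"v{i}" for i in rng.permutation(n_nodes)]
    edges: list[tuple[str, str]] = []
    for i in range(n_nodes):
        for k in range(i + 1, n_nodes):
            if rng.random() < edge_density:
                edges.append((order[i], order[k]))
    if not edges:
        edges.append((order[0], order[-1]))
    has_in = {v for _, v in edges}
    has_out = {u for u, _ in edges}
    nodes = sorted(set(order), key=order.index)
    g = SplicingGraph(
        gene_id=f"synth{seed}",
        nodes=nodes,
        edges=edges,
        node_cov={v: 0.0 for v in nodes},
        edge_cov={e: 0.0 for e in edges},
        sources=tuple(v for v in order if v not in has_in),
        sinks=tuple(v for v in order if v not in has_out),
    )
    return g.validate()


def draw_expressions(rng: np.random.Generator, n: int,
                     scale: float = DEFAULT_EXPRESSION_SCALE) -> np.ndarray:
    """Lognormal(-4, 1) expression levels, scaled and rounded to >= 1."""
    raw = rng.lognormal(mean=LOGNORMAL_MEAN, sigma=LOGNORMAL_SIGMA, size=n)
    return np.maximum(1, np.rint(raw * scale)).astype(np.int64)


def _random_walk(g: SplicingGraph, rng: np.random.Generator) -> tuple[str, ...]:
    out_adj: dict[str, list[str]] = {v: [] for v in g.nodes}
    for u, v in g.edges:
        out_adj[u].append(v)
    sinks = set(g.sinks)
    node = g.sources[rng.integers(len(g.sources))]
    path = [node]
    while node not in sinks:
        nxt = out_adj[node]
        node = nxt[rng.integers(len(nxt))]
        path.append(node)
    return tuple(path)


def sample_truth(
    g: SplicingGraph,
    k_paths: int,
    seed: int = 0,
    expression_scale: float = DEFAULT_EXPRESSION_SCALE,
) -> SyntheticInstance:
    """Sample ``k_paths`` truth transcripts and set coverages to their superposition.

    Duplicate walks are merged by summing their expressions; edges no walk
    uses keep coverage zero (a legal instance).
    """
    if k_paths < 1:
        raise ValueError("k_paths must be >= 1")
    rng = np.random.default_rng(seed)
    walks = [_random_walk(g, rng) for _ in range(k_paths)]
    exprs = draw_expressions(rng, k_paths, expression_scale)
    merged: dict[tuple[str, ...], int] = {}
    for w, e in zip(walks, exprs):
        merged[w] = merged.get(w, 0) + int(e)
    paths = [TranscriptPath(w, e) for w, e in merged.items()]

    out = g.copy()
    out.node_cov = {v: 0 for v in g.nodes}
    out.edge_cov = {e: 0 for e in g.edges}
    for p in paths:
        for v in p.nodes:
            out.node_cov[v] += p.expression
        for e in zip(p.nodes, p.nodes[1:]):
            out.edge_cov[e] += p.expression
    return SyntheticInstance(graph=out, truth_paths=paths, seed=seed)


def perturb(inst: SyntheticInstance, noise: NoiseSpec, seed: int = 0) -> SyntheticInstance:
    """Independently perturb every coverage; ground truth is untouched."""
    if noise.kind == "none" or (noise.kind == "mgauss" and noise.sigma == 0):
        return inst
    rng = np.random.default_rng(seed)

    def draw(cov: float) -> int:
        if noise.kind == "mgauss":
            return int(round(cov * max(0.0, 1.0 + noise.sigma * rng.standard_normal())))
        return int(rng.poisson(cov))

    g = inst.graph.copy()
    g.node_cov = {v: draw(c) for v, c in g.node_cov.items()}
    g.edge_cov = {e: draw(c) for e, c in g.edge_cov.items()}
    return replace(inst, graph=g, noise=noise)


def attach_sequences(
    inst: SyntheticInstance, seed: int = 0, length_range: tuple[int, int] = (50, 300)
) -> SyntheticInstance:
    """Give every exon a random nucleotide sequence (for evaluation tests)."""
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    alphabet = np.array(list("ACGT"))
    seqs = {
        v: "".join(alphabet[rng.integers(0, 4, size=rng.integers(lo, hi + 1))])
        for v in inst.graph.nodes
    }
    return replace(inst, sequences=seqs)


def parallel_chains_instance(
    k: int,
    seed: int = 0,
    chain_length: tuple[int, int] = (2, 4),
    expression_scale: float = DEFAULT_EXPRESSION_SCALE,
) -> SyntheticInstance:
    """Instance with ``k`` edge-disjoint truth paths through a shared source/sink.

    Each path is source -> private exon chain -> sink, so the truth
    decomposition is unique up to expression ties and exactly recoverable
    from noise-free coverages.
    """
    rng = np.random.default_rng(seed)
    nodes = ["s"]
    edges: list[tuple[str, str]] = []
    walks: list[tuple[str, ...]] = []
    for i in range(k):
        length = int(rng.integers(chain_length[0], chain_length[1] + 1))
        chain = [f"c{i}_{p}" for p in range(length)]
        nodes.extend(chain)
        walk = ["s", *chain, "t"]
        edges.extend(zip(walk, walk[1:]))
        walks.append(tuple(walk))
    nodes.append("t")
    exprs = draw_expressions(rng, k, expression_scale)
    paths = [TranscriptPath(w, int(e)) for w, e in zip(walks, exprs)]
    g = SplicingGraph(
        gene_id=f"chains{seed}",
        nodes=nodes,
        edges=edges,
        node_cov={v: 0 for v in nodes},
        edge_cov={e: 0 for e in edges},
        sources=("s",),
        sinks=("t",),
    )
    for p in paths:
        for v in p.nodes:
            g.node_cov[v] += p.expression
        for e in zip(p.nodes, p.nodes[1:]):
            g.edge_cov[e] += p.expression
    g.validate()
    return SyntheticInstance(graph=g, truth_paths=paths, seed=seed)
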