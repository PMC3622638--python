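"""Shared fixtures: tiny hand-built instances and the synthetic battery."""

from __future__ import annotations

import numpy as np
import pytest

from isoflow.graph_io import CostModel, SplicingGraph
from isoflow.offset_network import JunctionGraph
from isoflow import synthetic_data as sd


def make_junction_graph(edges_with_cov, sources, sinks) -> JunctionGraph:
    """Build a native (non-split) junction graph from (u, v, cov) triples."""
    j = JunctionGraph()
    seen = []
    for u, v, c in edges_with_cov:
        for n in (u, v):
            if n not in seen:
                seen.append(n)
        e = (u, v)
        j.edges.append(e)
        j.edge_cov[e] = c
        j.edge_family[e] = None
    j.nodes = seen
    j.sources = tuple(sources)
    j.sinks = tuple(sinks)
    return j


@pytest.fixture
def diamond():
    """Two-path junction instance with inconsistent coverages (optimum 2)."""
    return make_junction_graph(
        [("s", "a", 3), ("a", "t", 4), ("s", "b", 2), ("b", "t", 1)],
        sources=["s"],
        sinks=["t"],
    )


@pytest.fixture
def two_exon_graph():
    """Smallest valid splicing graph: s -> t, all coverages 5."""
    return SplicingGraph(
        gene_id="g1",
        nodes=["s", "t"],
        edges=[("s", "t")],
        node_cov={"s": 5, "t": 5},
        edge_cov={("s", "t"): 5},
        sources=("s",),
        sinks=("t",),
    ).validate()


def random_junction_instance(seed: int, max_edges: int = 6, max_cov: int = 4):
    """Small random UTEJC instance for brute-force cross-checks."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 6))
    g = sd.generate_dag(n, edge_density=float(rng.uniform(0.3, 0.9)), seed=seed)
    while len(g.edges) > max_edges:
        n -= 1
        g = sd.generate_dag(max(n, 2), 0.4, seed=seed)
    connected = {u for u, _ in g.edges} | {v for _, v in g.edges}
    j = make_junction_graph(
        [(u, v, int(rng.integers(0, max_cov + 1))) for u, v in g.edges],
        sources=[s for s in g.sources if s in connected],
        sinks=[t for t in g.sinks if t in connected],
    )
    return j


def battery_instance(i: int, expression_scale: float = 200.0) -> sd.SyntheticInstance:
    """Deterministic member of the varied synthetic battery."""
    rng = np.random.default_rng(10_000 + i)
    n_nodes = int(rng.integers(2, 31))
    density = float(rng.uniform(0.1, 0.5))
    k_paths = int(rng.integers(1, 7))
    g = sd.generate_dag(n_nodes, density, seed=20_000 + i)
    inst = sd.sample_truth(g, k_paths, seed=30_000 + i,
                           expression_scale=expression_scale)
    kind = ("none", "mgauss", "poisson")[i % 3]
    noise = sd.NoiseSpec(kind, 0.05 if kind == "mgauss" else 0.0)
    return sd.perturb(inst, noise, seed=40_000 + i)


@pytest.fixture(scope="session")
def battery():
    """200 varied synthetic instances (sizes, densities, paths, noise)."""
    return [battery_instance(i) for i in range(200)]
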