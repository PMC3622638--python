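"""End-to-end assembly: splicing graph in, weighted transcript paths out."""

from __future__ import annotations

from dataclasses import dataclass

from .graph_io import CostModel, SplicingGraph, scale_to_integer
from .mincost_solver import Flow, canonicalize, solve
from .offset_network import JunctionGraph, build_offset_network, split_nodes
from .path_extraction import (
    TranscriptPath,
    decompose,
    reconstruct_flow,
    superpose,
    utejc_objective,
)

__all__ = ["AssemblyResult", "assemble"]


@dataclass
class AssemblyResult:
    gene_id: str
    paths: list[TranscriptPath]
    objective: float
    junction: JunctionGraph
    flow: dict
    offset_flow: Flow


def assemble(
    g: SplicingGraph,
    cost_family: str = "squared",
    scale: float = 1.0,
) -> AssemblyResult:
    """Estimate transcripts and expression levels for one gene.

    Discretizes coverages, splits nodes into a junction graph, solves the
    min-cost offset flow under ``cost_family``, reconstructs the
    expression flow and decomposes it greedily into heaviest paths.  The
    returned objective is the summed deviation cost of the paths, which
    equals the solver's optimum.
    """
    cm = CostModel(cost_family)
    gi = scale_to_integer(g.copy().validate(), scale)
    j = split_nodes(gi)
    network = build_offset_network(j, cm)
    x_star = canonicalize(solve(network))
    x = reconstruct_flow(x_star, j)
    paths = decompose(j, x)
    if superpose(j, paths) != x:  # decomposition identity, checked on every run
        raise AssertionError("path superposition does not reproduce the flow")
    objective = utejc_objective(j, x, cm)
    return AssemblyResult(
        gene_id=g.gene_id,
        paths=paths,
        objective=objective,
        junction=j,
        flow=x,
        offset_flow=x_star,
    )
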