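# Methods

This note records the model implemented by `isoflow`, the assumptions it
makes, the numerical choices in the solver, what the synthetic generator
does and does not emulate, and known limitations.

## Problem statement

Input: a splicing graph — a directed acyclic graph `G = (V, E)` with at
least one source and one sink, a non-negative coverage `cov(e)` on every
edge and (optionally) every node, and a convex cost family per element.
Every node must lie on some source-to-sink path; sources have in-degree 0
and sinks out-degree 0.

Output: a multiset of source-to-sink paths `P₁ … P_k` with positive integer
expressions `w₁ … w_k` minimising

```
Σ_e f_e( | x(e) − cov(e) | ),   x(e) = Σ_{i : e ∈ P_i} w_i
```

Two objective variants are implemented. The *edge-only* variant sums over
edges only. The *node + edge* variant also scores node coverages; it is
reduced to the edge-only variant by splitting each node `v` into
`v_in → v_out`, placing `cov(v)` and the node's cost family on the
connecting arc, and rewiring each edge `(u, v)` to `(u_out, v_in)`.
All downstream machinery operates on the split ("junction") graph.

Cost families (`f` applied to the absolute deviation `x`):

| family | `f(x)` | notes |
| --- | --- | --- |
| `squared` | `x²` | default; strictly convex, penalises large deviations |
| `absolute` | `x` | linear; robust, may have non-unique optima |
| `sqrt_normalized` | `x / √cov` | variance-stabilised; falls back to `x` when `cov = 0` |

Coverages must be non-negative integers. Fractional inputs are handled by
`scale_to_integer`, which multiplies by a user-chosen scale and rounds half
away from zero; the solve is exact for the scaled integer problem.

## Offset network

Rather than solving for the flow `x` directly, the solver works with the
*offsets* `x − cov`. For each junction edge `(u, v)` the offset network has:

- a **forward arc** `u → v` with capacity `B` and the edge's cost family,
  carrying flow above the observed coverage, and
- a **reverse arc** `v → u` with capacity `cov(u, v)` and the same cost
  family, carrying flow below it,

where `B` is the total coverage plus one — large enough never to bind at an
optimum. Observed coverages are generally not conservative; the per-node
surplus `out-cov(v) − in-cov(v)` is absorbed by a zero-cost arc of exactly
that capacity to a collector node (surplus) or from a distributor node
(deficit), with matching exogenous injections `q`. Zero-cost auxiliary arcs
connect a super-source to the graph's sources, its sinks to a super-sink,
and the super-sink back to the super-source (capacity `B`), closing the
circulation. By construction `Σ q = 0`, which the builder asserts.

A feasible flow on this network corresponds one-to-one with a conservative
edge flow on the junction graph via

```
x(u, v) = cov(u, v) + x*_fwd(u, v) − x*_rev(u, v)
```

and has the same cost. Optimal offsets are first **canonicalised** by
cancelling `min(x*_fwd, x*_rev)` on each edge pair; since costs are
non-decreasing this never increases the cost, and it makes the
reconstruction non-negative.

## Exact convex min-cost flow

Because every arc cost is convex in its flow, the integer problem is
equivalent to a linear min-cost flow on a network where each capacity-`b`
arc is expanded into `b` unit arcs with marginal costs
`f(1) − f(0), f(2) − f(1), …` (non-decreasing, so unit arcs are used in
order). `convexify()` materialises this expansion (guarded by a
2,000,000-arc limit) and exists mainly as a checkable reference; the
production path in `solve()` performs the *implicit* equivalent:

- successive shortest augmenting paths from the distributor to the
  collector node, using Dijkstra with node potentials on reduced costs;
- the residual cost of pushing one more unit on an arc at flow `x` is the
  marginal `f(x+1) − f(x)`, and of removing one is `−(f(x) − f(x−1))`;
- on an augmenting path consisting solely of linear/zero-cost arcs, the
  full bottleneck is pushed at once; a path through any non-linear arc
  pushes one unit (its marginal changes after each unit).

With squared costs and `sqrt_normalized` the reduced costs are floats;
tiny negative reduced costs from rounding are clamped to zero. Ties in
Dijkstra are broken by insertion order (a heap counter) and arcs are
scanned in construction order, making the solver fully deterministic.
Infeasibility (which cannot occur for networks built by
`build_offset_network`) raises `InfeasibleFlowError`; a non-convex cost
model raises `NonConvexCostError` from `convexify`.

The block-push rule is what makes realistic coverage scales cheap: for
consistent coverages the entire surplus is routed through zero-cost
auxiliary arcs in a handful of augmentations, and only noise-induced
offsets (typically a few percent of coverage) require unit pushes through
non-linear arcs.

## Flow reconstruction and path decomposition

The reconstructed flow is checked with exact integer arithmetic:
conservation at every internal node, and total source out-flow equal to
total sink in-flow. Decomposition repeatedly extracts the
**heaviest-bottleneck path**: dynamic programming over a topological order
computes, for each node, the largest bottleneck of any source path reaching
it, breaking ties toward the topologically earliest predecessor and sink.
The path's full bottleneck is subtracted and the path recorded with that
weight. Properties guaranteed (and asserted):

- at most `|E|` paths are produced (each iteration zeroes at least one
  edge);
- path weights are non-increasing;
- the paths superpose exactly back to the flow, so their objective equals
  the solver's optimum — optimality transfers from flows to path sets.

Split-graph paths are merged back to original node ids before reporting.
Decomposition of a given flow into paths is generally not unique; the
tie-breaking above picks one canonical decomposition deterministically.

## Evaluation

Predicted transcripts (sequence + expression) are compared to a ground
truth set by minimum-cost bipartite matching (`scipy`'s Hungarian solver),
padding the smaller side with empty transcripts. The pair cost is the
number of bits needed to encode the truth given the prediction:

- the edit distance `d` (Levenshtein, computed by a vectorised row DP) is
  encoded as the Elias gamma code of `d + 1`;
- each edit in a canonical minimal edit script is encoded as the gamma code
  of (gap to the previous edit + 1), a 2-bit operation type
  (substitution/insertion/deletion), and a 2-bit symbol for operations that
  introduce one;
- the signed expression difference is folded to a positive integer by the
  bijection `x ↦ 2x (x > 0), 2|x| + 1 (x ≤ 0)` and gamma-coded.

The traceback prefers match > substitution > deletion > insertion, making
the script (and hence the encoded length) deterministic. The **bit score**
of a pair normalises the sequence-coding bits by the cost of encoding the
truth from scratch (`γ(|T| + 1) + 5|T|` bits); 0 is a perfect prediction,
1 is no better than nothing. A matched pair counts as a true positive when
its bit score is at most the bitscore threshold and its relative expression
error at most the expression threshold (pass `None` to disable the
expression test); precision, recall and F follow in the usual way.

## Synthetic generator

`generate_dag` draws a random topological order and includes each forward
edge independently with the given density; in-degree-0 nodes become
sources, out-degree-0 nodes sinks. `sample_truth` draws `k` random
source-to-sink walks, assigns each a log-normal expression
(`exp(N(−4, 1))`, scaled by `expression_scale`, default `10⁶`, rounded to
an integer ≥ 1; duplicate walks merge by summing), and sets every node and
edge coverage to the exact superposition. `perturb` applies multiplicative
Gaussian noise (`cov · max(0, 1 + σZ)`, rounded) or Poisson resampling to
the coverages only, leaving the truth untouched. `attach_sequences` gives
each exon a random 50–300 nt ACGT sequence. `parallel_chains_instance`
builds `k` edge-disjoint chains through a shared source and sink — the
identifiable regime where exact recovery is expected.

The generator emulates the *graph-level* abstraction only: exact or noisy
coverages on a known splicing graph. It does not simulate reads,
alignment/mapping errors, graph-construction errors, positional coverage
bias, or multi-gene interactions; conclusions drawn from it are about the
optimisation and evaluation layers, not about upstream read processing.

## Problem sizes and test design

The test suite and the acceptance script run on sizes chosen to keep the
full suite under a minute while exercising every code path: a 200-instance
battery with 2–30 nodes, densities 0.1–0.5, 1–6 truth paths, coverage
scale 200, and a none/Gaussian/Poisson noise rotation; brute-force
enumeration oracles on instances with at most 6 edges and flows up to 10;
noisy-recovery studies at coverage scale 10⁴ (so the ±1 integer
quantisation is negligible against the 20% tolerance). The generator's
default `expression_scale` remains 10⁶; the implicit-convexification solver
handles that scale routinely because consistent flow moves in bottleneck
blocks.

## Limitations

- Expressions and coverages are integers; sub-unit expression resolution
  requires pre-scaling via `scale_to_integer`.
- The decomposition is greedy by bottleneck weight. It attains the optimal
  *objective* exactly, but among the (possibly many) optimal path sets it
  returns one canonical choice; it does not search for, e.g., the smallest
  number of paths explaining the flow (that problem is NP-hard).
- With the `absolute` family the optimal flow itself may be non-unique; the
  deterministic solver picks one optimum.
- `sqrt_normalized` costs are irrational; optimality holds up to float
  round-off (reduced costs are clamped at zero), whereas `squared` and
  `absolute` are solved in exact integer arithmetic.
- Unit-arc convexification via `convexify()` is pseudo-polynomial and
  refuses expansions beyond 2,000,000 arcs; use `solve()` (implicit
  expansion) for realistic coverages.
- The evaluation's edit-script coding assumes the ACGT alphabet (2-bit
  symbols).
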