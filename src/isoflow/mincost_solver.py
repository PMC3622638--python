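"""Exact integer min-cost flow with convex arc costs.

The offset network's arc costs are convex with ``f(0) = 0``.  A classical
reduction replaces an arc of capacity ``b`` by ``b`` parallel unit arcs
whose i-th copy costs the marginal ``f(i) - f(i-1)``; convexity makes the
marginals nondecreasing, so any min-cost solution fills copies in order
and its cost telescopes back to ``f(x)``.  ``convexify`` materializes this
expansion (pseudo-polynomial — intended for inspection and small
instances).

``solve`` runs successive shortest augmenting paths with node potentials
directly on the *implicit* expansion: at current flow ``x`` the residual
forward cost of an arc is the next marginal ``f(x+1) - f(x)`` and the
residual backward cost is ``-(f(x) - f(x-1))``.  This is arc-for-arc the
same search space as the explicit expansion without ever materializing
it, and it is exact on integers.  Augmentations push one unit through
nonlinear arcs (the marginal changes per unit) and whole residual blocks
through linear/zero-cost arcs, which keeps the common consistent-coverage
case fast.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

from .offset_network import Arc, OffsetNetwork, S_STAR, T_STAR

__all__ = [
    "Flow",
    "LinearArc",
    "ConvexifiedNetwork",
    "NonConvexCostError",
    "InfeasibleFlowError",
    "convexify",
    "solve",
    "canonicalize",
]


class NonConvexCostError(ValueError):
    """Cost marginals decrease somewhere: the unit-arc reduction is invalid."""


class InfeasibleFlowError(RuntimeError):
    """No flow meets the exogenous demands (signals a construction bug)."""


@dataclass
class Flow:
    """Integer flow on an offset network; ``values[i]`` is the flow on arc i."""

    network: OffsetNetwork
    values: list[int]

    @property
    def cost(self) -> float:
        return sum(a.cost(x) for a, x in zip(self.network.arcs, self.values))

    def check(self) -> None:
        """Verify capacity and conservation constraints exactly."""
        net = self.network
        balance = {n: 0 for n in net.nodes}
        for a, x in zip(net.arcs, self.values):
            if not (0 <= x <= a.cap):
                raise AssertionError(f"flow {x} violates capacity on {a}")
            balance[a.u] += x
            balance[a.v] -= x
        for n, b in balance.items():
            if b != net.q.get(n, 0):
                raise AssertionError(f"conservation violated at {n}: {b} != q")


@dataclass(frozen=True)
class LinearArc:
    u: object
    v: object
    cap: int
    unit_cost: float
    origin: int  # index of the offset-network arc this copy expands


@dataclass
class ConvexifiedNetwork:
    nodes: list
    arcs: list[LinearArc]
    q: dict


def convexify(n: OffsetNetwork, max_expansion: int = 2_000_000) -> ConvexifiedNetwork:
    """Expand convex-cost arcs into parallel unit-capacity linear arcs.

    Zero-cost arcs are kept intact.  Raises :class:`NonConvexCostError` if
    a cost model yields decreasing marginals, and ``ValueError`` when the
    expansion would exceed ``max_expansion`` arcs (the reduction is
    pseudo-polynomial; use :func:`solve` instead at scale).
    """
    arcs: list[LinearArc] = []
    total = 0
    for i, a in enumerate(n.arcs):
        if a.model is None:
            arcs.append(LinearArc(a.u, a.v, a.cap, 0.0, i))
            continue
        total += a.cap
        if total > max_expansion:
            raise ValueError("unit-arc expansion too large; solve implicitly instead")
        prev = None
        for k in range(1, a.cap + 1):
            m = a.marginal(k)
            if prev is not None and m < prev:
                raise NonConvexCostError(
                    f"marginal cost decreases at unit {k} on arc {a.u}->{a.v}")
            prev = m
            arcs.append(LinearArc(a.u, a.v, 1, m, i))
    return ConvexifiedNetwork(nodes=list(n.nodes), arcs=arcs, q=dict(n.q))


def solve(n: OffsetNetwork) -> Flow:
    """Find a minimum-cost integer flow on the offset network.

    Successive shortest paths with node potentials over the residual
    graph of the implicit unit-arc expansion.  Deterministic: arc order
    and heap tie-breaking are fixed by the network's arc list.
    """
    node_ix = {v: i for i, v in enumerate(n.nodes)}
    nn = len(n.nodes)
    arcs = n.arcs
    x = [0] * len(arcs)

    # adjacency: per node, (arc index, +1 forward residual / -1 backward)
    adj: list[list[tuple[int, int]]] = [[] for _ in range(nn)]
    for i, a in enumerate(arcs):
        adj[node_ix[a.u]].append((i, 1))
        adj[node_ix[a.v]].append((i, -1))

    supply = n.q.get(S_STAR, 0)
    if supply == 0:
        flow = Flow(n, x)
        flow.check()
        return flow
    src, dst = node_ix[S_STAR], node_ix[T_STAR]

    INF = float("inf")
    pi = [0.0] * nn

    while supply > 0:
        dist = [INF] * nn
        parent: list[tuple[int, int] | None] = [None] * nn
        dist[src] = 0.0
        heap: list[tuple[float, int, int]] = [(0.0, 0, src)]
        counter = 1
        done = [False] * nn
        while heap:
            d, _, u = heapq.heappop(heap)
            if done[u]:
                continue
            done[u] = True
            if u == dst:
                break
            for ai, direction in adj[u]:
                a = arcs[ai]
                if direction == 1:
                    if x[ai] >= a.cap:
                        continue
                    w = node_ix[a.v]
                    c = a.marginal(x[ai] + 1)
                else:
                    if x[ai] <= 0:
                        continue
                    w = node_ix[a.u]
                    c = -a.marginal(x[ai])
                if done[w]:
                    continue
                rc = c + pi[u] - pi[w]
                if rc < 0:  # float slack on sqrt-normalized costs
                    rc = 0.0
                nd = d + rc
                if nd < dist[w]:
                    dist[w] = nd
                    parent[w] = (ai, direction)
                    heapq.heappush(heap, (nd, counter, w))
                    counter += 1
        if dist[dst] == INF:
            raise InfeasibleFlowError("exogenous demand cannot be met")

        dt = dist[dst]
        for v in range(nn):
            pi[v] += dist[v] if dist[v] < dt else dt

        # trace path, find admissible push
        path: list[tuple[int, int]] = []
        v = dst
        while v != src:
            ai, direction = parent[v]  # type: ignore[misc]
            path.append((ai, direction))
            a = arcs[ai]
            v = node_ix[a.u] if direction == 1 else node_ix[a.v]
        delta = supply
        for ai, direction in path:
            a = arcs[ai]
            resid = (a.cap - x[ai]) if direction == 1 else x[ai]
            if not a.is_linear():
                resid = min(resid, 1)  # marginal changes per unit
            delta = min(delta, resid)
        for ai, direction in path:
            x[ai] += delta if direction == 1 else -delta
        supply -= delta

    flow = Flow(n, x)
    flow.check()
    return flow


def canonicalize(flow: Flow) -> Flow:
    """Cancel opposing offsets so at most one direction per edge is nonzero.

    Subtracting ``min(x_uv, x_vu)`` from both directions of a junction
    edge preserves feasibility and never increases the cost (strictly
    decreases it for strictly increasing cost families, so an optimal
    flow is typically already canonical).
    """
    values = list(flow.values)
    for fwd, rev in flow.network.arc_pairs().values():
        m = min(values[fwd], values[rev])
        if m:
            values[fwd] -= m
            values[rev] -= m
    out = Flow(flow.network, values)
    out.check()
    return out
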