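"""Maximum-confidence ("strongest") path search and ε-suboptimal subnetworks.

The strongest path between a source set A and a target set B is the simple
path maximizing the product of its edge confidences, with a constant penalty
factor D ∈ (0,1] multiplied in once per edge so that, among near-equal
products, shorter chains win.  Maximizing ``product(P(e)) * D**len`` is
equivalent to minimizing the additive length of the same path in a *dual*
graph where every edge is reweighted to

    W(e) = -(ln D + ln P(e))  >=  0,

so a single nonnegative-weight shortest-path (Dijkstra) pass finds the exact
optimum in polynomial time — the unpenalized max-product problem on general
graphs is intractable, the (0,1] weight range plus the log transform is what
makes it easy.  Multi-source/multi-sink search reduces to single-pair by
adding a super-source σ wired to every a ∈ A and a super-sink τ wired from
every b ∈ B with zero-weight artificial edges (zero, not W(1, D): the length
penalty must not be charged for artificial hops).

Suboptimal search: for ε ≥ 0 (in dual-length, i.e. natural-log units), an
ε-strongest path is any A→B path whose dual length is within ε of the optimum
w*.  Enumerating those paths is exponential, but the *node set* V_ε — nodes
seen on at least one ε-strongest path — comes from just two Dijkstra passes:
a(v) = dual distance from A to v (forward), b(v) = dual distance from v to B
(backward on the reversed dual), and

    V_ε = { v : a(v) + b(v) <= w* + ε }.

Dense output is the induced subgraph on V_ε; sparse output keeps only edges
(u,v) with a(u) + W(u,v) + b(v) <= w* + ε, i.e. edges that themselves lie on
some ε-strongest path.  BFS hop layers from A over the retained subnetwork
are attached for downstream layout/reporting.

Determinism: ties are broken first by fewer edges (beyond what D < 1 already
enforces — exact dual-length ties can still occur), then by lexicographically
smallest label sequence, so repeated runs return byte-identical results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from heapq import heappop, heappush
from typing import Iterable, Sequence

from .errors import InputError
from .network import ConfidenceNetwork

__all__ = [
    "DEFAULT_DAMPING",
    "dual_weight",
    "build_dual",
    "strongest_path",
    "epsilon_subnetwork",
    "DualGraph",
    "PathResult",
    "EpsilonSubnetwork",
]

DEFAULT_DAMPING = 0.95
_TOL = 1e-9

_INF = math.inf


def dual_weight(p: float, d: float) -> float:
    """Dual edge weight W = -(ln d + ln p); nonnegative for p, d ∈ (0,1]."""
    if not 0.0 < p <= 1.0:
        raise InputError(f"confidence {p} outside (0, 1]")
    if not 0.0 < d <= 1.0:
        raise InputError(f"penalty factor {d} outside (0, 1]")
    return -(math.log(d) + math.log(p))


@dataclass
class DualGraph:
    """Adjacency view of the dual graph with super-source/super-sink.

    Real nodes keep their network indices; σ = n_labels and τ = n_labels + 1.
    Each adjacency entry is ``(neighbor, W, hop)`` where hop is 1 for real
    edges and 0 for the artificial super edges.
    """

    net: ConfidenceNetwork
    sources: frozenset[int]
    targets: frozenset[int]
    d: float
    sigma: int
    tau: int
    forward: dict[int, list[tuple[int, float, int]]] = field(default_factory=dict)
    backward: dict[int, list[tuple[int, float, int]]] = field(default_factory=dict)


def build_dual(
    net: ConfidenceNetwork,
    sources: Iterable[int],
    targets: Iterable[int],
    d: float = DEFAULT_DAMPING,
) -> DualGraph:
    """Reweight every edge by :func:`dual_weight` and attach σ/τ.

    Sources and targets must be non-empty, disjoint, and present in the
    network.
    """
    if not 0.0 < d <= 1.0:
        raise InputError(f"penalty factor {d} outside (0, 1]")
    A = frozenset(sources)
    B = frozenset(targets)
    if not A or not B:
        raise InputError("source and target sets must be non-empty")
    if A & B:
        both = sorted(net.labels[i] for i in A & B)
        raise InputError(f"source and target sets must be disjoint; shared: {both}")
    missing = (A | B) - net.nodes
    if missing:
        raise InputError(f"nodes not in network: {sorted(missing)}")

    sigma = len(net.labels)
    tau = sigma + 1
    fwd: dict[int, list[tuple[int, float, int]]] = {
        u: [] for u in (*net.nodes, sigma, tau)
    }
    bwd: dict[int, list[tuple[int, float, int]]] = {
        u: [] for u in (*net.nodes, sigma, tau)
    }

    def add(u: int, v: int, w: float, hop: int) -> None:
        fwd[u].append((v, w, hop))
        bwd[v].append((u, w, hop))

    for (u, v), p in net.edges.items():
        w = dual_weight(p, d)
        add(u, v, w, 1)
        if not net.directed:
            add(v, u, w, 1)
    for a in A:
        add(sigma, a, 0.0, 0)
    for b in B:
        add(b, tau, 0.0, 0)
    return DualGraph(
        net=net, sources=A, targets=B, d=d, sigma=sigma, tau=tau,
        forward=fwd, backward=bwd,
    )


def _dijkstra(
    adj: dict[int, list[tuple[int, float, int]]], start: int
) -> tuple[dict[int, float], dict[int, int]]:
    """Shortest paths under the lexicographic key (dual length, hop count).

    Both components are additive with nonnegative edge contributions, so
    Dijkstra applies to the pair directly.  Returns (dist, hops); nodes that
    are unreachable are absent.
    """
    dist: dict[int, float] = {}
    hops: dict[int, int] = {}
    heap: list[tuple[float, int, int]] = [(0.0, 0, start)]
    while heap:
        du, hu, u = heappop(heap)
        if u in dist:
            continue
        dist[u] = du
        hops[u] = hu
        for v, w, hop in adj[u]:
            if v not in dist:
                heappush(heap, (du + w, hu + hop, v))
    return dist, hops


@dataclass(frozen=True)
class PathResult:
    """One strongest path (super nodes stripped), or a no-path marker.

    ``penalized_score = product * d**edge_count`` is the quantity the search
    maximizes; ``dual_length`` is its additive mirror, -ln(penalized_score).
    """

    nodes: tuple[int, ...]
    labels: tuple[str, ...]
    edge_count: int
    product: float
    penalized_score: float
    dual_length: float
    d: float

    @property
    def exists(self) -> bool:
        return bool(self.nodes)

    @classmethod
    def no_path(cls, d: float) -> "PathResult":
        return cls(
            nodes=(), labels=(), edge_count=0, product=0.0,
            penalized_score=0.0, dual_length=_INF, d=d,
        )


def _reconstruct(
    dual: DualGraph,
    dist_f: dict[int, float],
    hops_f: dict[int, int],
    dist_b: dict[int, float],
    hops_b: dict[int, int],
) -> list[int]:
    """Walk σ→τ through the tight-edge DAG choosing the smallest label.

    An edge (u,v) lies on some optimal path iff dist_f(u) + W + dist_b(v)
    equals w* and the hop counts likewise sum to the optimal hop count; every
    prefix of an optimal path is itself tight, so a greedy forward walk that
    always picks the lexicographically smallest tight successor yields the
    smallest label sequence among (min-length, min-hop) optimal paths.
    """
    w_star = dist_f[dual.tau]
    h_star = hops_f[dual.tau]
    labels = dual.net.labels
    path: list[int] = []
    u = dual.sigma
    while u != dual.tau:
        best: tuple[str, int] | None = None
        for v, w, hop in dual.forward[u]:
            if v not in dist_b:
                continue
            if abs(dist_f[u] + w + dist_b[v] - w_star) > _TOL:
                continue
            if hops_f[u] + hop + hops_b[v] != h_star:
                continue
            # dist_f/hops_f of v on a tight continuation equal the prefix sums
            if abs(dist_f[v] - (dist_f[u] + w)) > _TOL:
                continue
            key = ("" if v == dual.tau else labels[v], v)
            if best is None or key < best:
                best = key
        assert best is not None, "tight successor must exist on an optimal path"
        u = best[1]
        if u != dual.tau:
            path.append(u)
    return path


def strongest_path(
    net: ConfidenceNetwork,
    sources: Iterable[int],
    targets: Iterable[int],
    d: float = DEFAULT_DAMPING,
) -> PathResult:
    """The A→B path maximizing ``product(P(e)) * d**edge_count``.

    Exact dual-length ties are broken toward fewer edges, then toward the
    lexicographically smallest label sequence.  When no source can reach any
    target, a first-class no-path result is returned (``result.exists`` is
    False) rather than raising — batch runs over many databases must carry on
    past empty ones.
    """
    dual = build_dual(net, sources, targets, d)
    dist_f, hops_f = _dijkstra(dual.forward, dual.sigma)
    if dual.tau not in dist_f:
        return PathResult.no_path(d)
    dist_b, hops_b = _dijkstra(dual.backward, dual.tau)
    nodes = _reconstruct(dual, dist_f, hops_f, dist_b, hops_b)

    product = 1.0
    for u, v in zip(nodes, nodes[1:]):
        product *= net.confidence(u, v)  # type: ignore[operator]
    edge_count = len(nodes) - 1
    penalized = product * d**edge_count
    return PathResult(
        nodes=tuple(nodes),
        labels=tuple(net.labels[i] for i in nodes),
        edge_count=edge_count,
        product=product,
        penalized_score=penalized,
        dual_length=dist_f[dual.tau],
        d=d,
    )


@dataclass(frozen=True)
class EpsilonSubnetwork:
    """The V_ε node set with its witnessing distances and retained edges.

    ``a``/``b`` are forward/backward dual distances for every node reachable
    in the respective direction; ``edges`` maps retained edges (canonical
    orientation) to their confidence; ``layers`` are BFS hop distances from
    the source set inside the retained subnetwork.
    """

    nodes: frozenset[int]
    a: dict[int, float]
    b: dict[int, float]
    w_star: float
    epsilon: float
    sparse: bool
    edges: dict[tuple[int, int], float]
    layers: dict[int, int]
    d: float

    @property
    def exists(self) -> bool:
        return bool(self.nodes)

    @classmethod
    def no_path(cls, epsilon: float, sparse: bool, d: float) -> "EpsilonSubnetwork":
        return cls(
            nodes=frozenset(), a={}, b={}, w_star=_INF, epsilon=epsilon,
            sparse=sparse, edges={}, layers={}, d=d,
        )


def epsilon_subnetwork(
    net: ConfidenceNetwork,
    sources: Iterable[int],
    targets: Iterable[int],
    d: float = DEFAULT_DAMPING,
    epsilon: float = 0.0,
    sparse: bool = False,
) -> EpsilonSubnetwork:
    """Nodes (and edges) lying within ε of the strongest path.

    ε is measured in dual-length units (natural log): a node v belongs to V_ε
    iff some A→B walk through v has dual length at most w* + ε, i.e.
    a(v) + b(v) <= w* + ε.  A small additive slack (1e-9) absorbs
    floating-point noise at the boundary.  At ε = 0, V_0 is exactly the set
    of nodes on optimal paths.
    """
    if epsilon < 0:
        raise InputError(f"epsilon must be >= 0, got {epsilon}")
    dual = build_dual(net, sources, targets, d)
    dist_f, _ = _dijkstra(dual.forward, dual.sigma)
    if dual.tau not in dist_f:
        return EpsilonSubnetwork.no_path(epsilon, sparse, d)
    dist_b, _ = _dijkstra(dual.backward, dual.tau)
    w_star = dist_f[dual.tau]
    cutoff = w_star + epsilon + _TOL

    a = {v: dist for v, dist in dist_f.items() if v < dual.sigma}
    b = {v: dist for v, dist in dist_b.items() if v < dual.sigma}
    members = frozenset(
        v for v in a if v in b and a[v] + b[v] <= cutoff
    )

    edges: dict[tuple[int, int], float] = {}
    for (u, v), p in net.edges.items():
        if u not in members or v not in members:
            continue
        if sparse:
            w = dual_weight(p, d)
            ok = a[u] + w + b[v] <= cutoff
            if not ok and not net.directed:
                ok = a[v] + w + b[u] <= cutoff
            if not ok:
                continue
        edges[(u, v)] = p

    layers = _bfs_layers(edges, net.directed, dual.sources & members)
    return EpsilonSubnetwork(
        nodes=members, a=a, b=b, w_star=w_star, epsilon=epsilon,
        sparse=sparse, edges=edges, layers=layers, d=d,
    )


def _bfs_layers(
    edges: dict[tuple[int, int], float],
    directed: bool,
    roots: Iterable[int],
) -> dict[int, int]:
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        if not directed:
            adj.setdefault(v, []).append(u)
    layers = {r: 0 for r in roots}
    frontier: Sequence[int] = sorted(layers)
    depth = 0
    while frontier:
        depth += 1
        nxt = []
        for u in frontier:
            for v in adj.get(u, ()):
                if v not in layers:
                    layers[v] = depth
                    nxt.append(v)
        frontier = sorted(nxt)
    return layers
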