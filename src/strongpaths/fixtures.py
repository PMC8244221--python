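"""Synthetic network generators and brute-force oracles.

Everything here exists so the search algorithms can be exercised and
cross-checked without downloading any interaction database: Erdős–Rényi-style
weighted networks, networks with a planted high-confidence chain whose
recovery is the ground truth, random signed networks, and an exhaustive
simple-path enumerator that serves as the independent optimum oracle on small
graphs.

All randomness flows from one integer seed through a private
``numpy.random.Generator``; generators never touch global random state, and
identical (spec, seed) pairs are bit-reproducible.  Labels are "n000",
"n001", ... so lexicographic tie-breaking is predictable in tests.
"""

from __future__ import annotations

from itertools import combinations, permutations
from typing import Iterable

import numpy as np

from .errors import InputError
from .network import ConfidenceNetwork
from .regulatory import SignedNetwork

__all__ = [
    "random_network",
    "planted_path_network",
    "brute_force_strongest",
    "random_signed_network",
]

_BRUTE_FORCE_MAX_NODES = 12


def _labels(n: int) -> list[str]:
    return [f"n{i:03d}" for i in range(n)]


def _pairs(n: int, directed: bool):
    return permutations(range(n), 2) if directed else combinations(range(n), 2)


def random_network(
    n_nodes: int,
    density: float,
    weight_range: tuple[float, float] = (0.2, 0.95),
    directed: bool = False,
    seed: int = 0,
) -> ConfidenceNetwork:
    """Erdős–Rényi G(n, p) with confidences uniform in *weight_range*."""
    if not 0.0 <= density <= 1.0:
        raise InputError(f"density must be in [0, 1], got {density}")
    lo, hi = weight_range
    if not 0.0 < lo <= hi <= 1.0:
        raise InputError(f"weight range {weight_range} not within (0, 1]")
    rng = np.random.default_rng(seed)
    edges: dict[tuple[int, int], float] = {}
    for u, v in _pairs(n_nodes, directed):
        if rng.random() < density:
            edges[(u, v)] = float(rng.uniform(lo, hi))
    return ConfidenceNetwork(directed=directed, labels=_labels(n_nodes), edges=edges)


def planted_path_network(
    n_nodes: int = 20,
    density: float = 0.2,
    length: int = 3,
    p_hi: float = 0.95,
    p_lo: float = 0.3,
    directed: bool = False,
    seed: int = 0,
) -> tuple[ConfidenceNetwork, list[int]]:
    """A high-confidence chain embedded in low-confidence background noise.

    Nodes 0..length form the chain (source 0, target ``length``, fresh
    intermediates in between) with every chain edge at confidence ``p_hi``;
    background edges are sampled at *density* with confidences uniform in
    (0.05, p_lo].  Returns the network and the ground-truth chain, for
    recovery tests: the chain is the unique strongest path whenever no short
    noise path beats ``p_hi**length * D**length``.
    """
    if length < 1:
        raise InputError(f"planted path length must be >= 1, got {length}")
    if n_nodes < length + 1:
        raise InputError(f"need >= {length + 1} nodes for a length-{length} chain")
    if p_hi <= p_lo:
        raise InputError(f"planted confidence {p_hi} must exceed cap {p_lo}")
    rng = np.random.default_rng(seed)
    chain = list(range(length + 1))
    chain_edges = set(zip(chain, chain[1:]))
    edges: dict[tuple[int, int], float] = {}
    for u, v in _pairs(n_nodes, directed):
        pair = (u, v) if directed else (min(u, v), max(u, v))
        if pair in chain_edges or (not directed and (pair[1], pair[0]) in chain_edges):
            continue
        if rng.random() < density:
            edges[(u, v)] = float(rng.uniform(0.05, p_lo))
    for u, v in chain_edges:
        edges[(u, v)] = p_hi
    net = ConfidenceNetwork(directed=directed, labels=_labels(n_nodes), edges=edges)
    return net, chain


def brute_force_strongest(
    net: ConfidenceNetwork,
    sources: Iterable[int],
    targets: Iterable[int],
    d: float = 0.95,
) -> tuple[float | None, list[tuple[int, ...]]]:
    """Exhaustive simple-path enumeration oracle.

    Scores every simple source→target path by ``product * d**len`` via
    depth-first search and returns ``(best_score, all argmax node
    sequences)``; ``(None, [])`` when no path exists.  Guarded to tiny
    graphs — this is an oracle, not an algorithm.
    """
    if net.n_nodes > _BRUTE_FORCE_MAX_NODES:
        raise InputError(
            f"brute-force oracle limited to {_BRUTE_FORCE_MAX_NODES} nodes, "
            f"got {net.n_nodes}"
        )
    A = sorted(set(sources))
    B = set(targets)
    adj = net.adjacency()
    best: float | None = None
    argmax: list[tuple[int, ...]] = []

    def visit(u: int, score: float, path: list[int], seen: set[int]) -> None:
        nonlocal best
        if u in B:
            # do not return: a continuation to another target is a distinct path
            if best is None or score > best + 1e-12:
                best = score
                argmax.clear()
                argmax.append(tuple(path))
            elif abs(score - best) <= 1e-12:
                argmax.append(tuple(path))
        for v, p in adj[u]:
            if v in seen:
                continue
            seen.add(v)
            path.append(v)
            visit(v, score * p * d, path, seen)
            path.pop()
            seen.remove(v)

    for s in A:
        if s in B:
            continue
        visit(s, 1.0, [s], {s})
    return best, argmax


def random_signed_network(
    n_nodes: int,
    density: float,
    inhibitory_fraction: float,
    seed: int = 0,
) -> SignedNetwork:
    """Directed Erdős–Rényi signed network; each edge -1 with the stated
    probability, else +1."""
    if not 0.0 <= density <= 1.0:
        raise InputError(f"density must be in [0, 1], got {density}")
    if not 0.0 <= inhibitory_fraction <= 1.0:
        raise InputError(
            f"inhibitory fraction must be in [0, 1], got {inhibitory_fraction}"
        )
    rng = np.random.default_rng(seed)
    adjacency: dict[int, dict[int, frozenset[int]]] = {}
    for u, v in permutations(range(n_nodes), 2):
        if rng.random() < density:
            sign = -1 if rng.random() < inhibitory_fraction else +1
            adjacency.setdefault(u, {})[v] = frozenset({sign})
    return SignedNetwork(labels=_labels(n_nodes), adjacency=adjacency)
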