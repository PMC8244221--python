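"""Signed regulatory paths in TF-target networks.

A signed network is a directed graph whose edges carry +1 (activation) or -1
(repression).  For each source/target pair the hop-minimal directed paths are
found by BFS, every minimal path is enumerated from the BFS predecessor DAG,
and each is classified by the product of its edge signs: +1 means the path is
activating (an even number of repressions — e.g. double repression activates),
-1 means inhibitory.

The edge-list dialect is tab-separated with at least three columns — source,
target, regulation mode — with mode strings matched case-insensitively:
``Activation`` → +1, ``Repression`` → -1, ``Unknown`` dropped by default (any
TRRUST-style dump works unmodified).  Parallel edges with conflicting signs
are kept as distinct edges, so one node chain may yield both an activating
and an inhibitory path.
"""

from __future__ import annotations

import itertools
import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from .annotation import AnnotationTable
from .errors import FormatError, InputError
from .network import ConfidenceNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "SignedNetwork",
    "RegulatoryPath",
    "RegulatoryResult",
    "parse_signed_network",
    "classify_path",
    "regulatory_paths",
]

_MODE_MAP = {"activation": +1, "repression": -1}


@dataclass
class SignedNetwork:
    """Directed graph with per-edge signs; parallel ± edges coexist."""

    labels: list[str]
    adjacency: dict[int, dict[int, frozenset[int]]] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return sum(len(s) for nbrs in self.adjacency.values() for s in nbrs.values())

    def signs(self, u: int, v: int) -> frozenset[int]:
        return self.adjacency.get(u, {}).get(v, frozenset())

    def annotation(self) -> AnnotationTable:
        return AnnotationTable.from_labels(self.labels)


def parse_signed_network(
    path: str | Path,
    table: AnnotationTable | None = None,
    unknown_policy: Literal["drop", "activation", "both"] = "drop",
) -> SignedNetwork:
    """Parse a signed edge list (source / target / mode, tab-separated).

    ``unknown_policy`` controls rows whose mode is ``Unknown``: drop them
    (default — the sign-product classification is defined only for ±1), treat
    them as activation, or keep both orientations of the sign.
    Unrecognized mode strings are a format error naming the line.
    """
    labels: list[str] = list(table.labels) if table is not None else []
    intern: dict[str, int] = {}
    adjacency: dict[int, dict[int, set[int]]] = {}
    n_unknown = 0
    n_rows = 0

    def node_id(name: str, lineno: int) -> int:
        name = name.strip()
        if not name:
            raise FormatError(f"{path}: line {lineno}: empty node name")
        if table is not None:
            return table.resolve_unique(name, context=f"{path}: line {lineno}")
        if name not in intern:
            intern[name] = len(labels)
            labels.append(name)
        return intern[name]

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 columns, got {len(cols)}"
                )
            mode = cols[2].strip().casefold()
            if mode == "unknown":
                n_unknown += 1
                if unknown_policy == "drop":
                    continue
                signs = {+1} if unknown_policy == "activation" else {+1, -1}
            elif mode in _MODE_MAP:
                signs = {_MODE_MAP[mode]}
            else:
                raise FormatError(
                    f"{path}: line {lineno}: unrecognized regulation mode "
                    f"{cols[2]!r}"
                )
            u = node_id(cols[0], lineno)
            v = node_id(cols[1], lineno)
            if u == v:
                continue
            adjacency.setdefault(u, {}).setdefault(v, set()).update(signs)
            n_rows += 1

    if n_unknown:
        logger.info(
            "%s: %d edge(s) with mode 'Unknown' (%s)", path, n_unknown,
            "dropped" if unknown_policy == "drop" else f"policy={unknown_policy}",
        )
    frozen = {
        u: {v: frozenset(s) for v, s in nbrs.items()} for u, nbrs in adjacency.items()
    }
    return SignedNetwork(labels=labels, adjacency=frozen)


def classify_path(signs: Iterable[int]) -> str:
    """``"activating"`` if the sign product is +1, else ``"inhibitory"``.

    Equivalently: activating iff the number of -1 edges is even.  An empty
    path has no regulatory meaning and is rejected.
    """
    signs = list(signs)
    if not signs:
        raise InputError("cannot classify an empty path")
    if any(s not in (1, -1) for s in signs):
        raise InputError(f"signs must be +1/-1, got {signs}")
    prod = 1
    for s in signs:
        prod *= s
    return "activating" if prod == 1 else "inhibitory"


@dataclass(frozen=True)
class RegulatoryPath:
    source: int
    target: int
    nodes: tuple[int, ...]
    labels: tuple[str, ...]
    signs: tuple[int, ...]
    mode: str

    @property
    def length(self) -> int:
        return len(self.nodes) - 1


@dataclass
class RegulatoryResult:
    paths: list[RegulatoryPath] = field(default_factory=list)
    no_path_pairs: list[tuple[int, int]] = field(default_factory=list)
    truncated_pairs: list[tuple[int, int]] = field(default_factory=list)


def _bfs_dag(net: SignedNetwork, s: int) -> tuple[dict[int, int], dict[int, list[int]]]:
    """BFS distances from s plus the predecessor DAG over shortest paths."""
    dist = {s: 0}
    preds: dict[int, list[int]] = {}
    queue = deque([s])
    while queue:
        u = queue.popleft()
        for v in net.adjacency.get(u, {}):
            if v not in dist:
                dist[v] = dist[u] + 1
                preds[v] = [u]
                queue.append(v)
            elif dist[v] == dist[u] + 1:
                preds[v].append(u)
    return dist, preds


def _node_chains(
    preds: dict[int, list[int]], s: int, t: int, cap: int
) -> tuple[list[tuple[int, ...]], bool]:
    """All hop-minimal node chains s→t from the predecessor DAG (capped)."""
    chains: list[tuple[int, ...]] = []
    truncated = False
    stack: list[tuple[int, tuple[int, ...]]] = [(t, (t,))]
    while stack:
        u, suffix = stack.pop()
        if u == s:
            chains.append(suffix)
            if len(chains) >= cap:
                truncated = bool(stack)
                break
            continue
        for p in preds[u]:
            stack.append((p, (p,) + suffix))
    return chains, truncated


def regulatory_paths(
    net: SignedNetwork,
    sources: Iterable[int],
    targets: Iterable[int],
    mode_filter: Literal["activating", "inhibitory", "both"] = "both",
    max_paths_per_pair: int = 100,
) -> RegulatoryResult:
    """Hop-minimal signed paths for every (source, target) pair.

    Each pair is handled independently: BFS gives the pair's minimal hop
    count, every path of that length is enumerated via the predecessor DAG
    (with parallel ± edges expanding into one path per sign combination),
    classified, and filtered by *mode_filter*.  A node that is both source
    and target yields no path to itself.  Pairs with no connecting path are
    reported in ``no_path_pairs``; pairs where the per-pair cap was hit are
    flagged in ``truncated_pairs``.
    """
    if mode_filter not in ("activating", "inhibitory", "both"):
        raise InputError(f"bad mode filter {mode_filter!r}")
    A = sorted(set(sources))
    B = sorted(set(targets))
    if not A or not B:
        raise InputError("source and target sets must be non-empty")
    bad = [v for v in (*A, *B) if not 0 <= v < net.n_nodes]
    if bad:
        raise InputError(f"nodes not in network: {bad}")

    result = RegulatoryResult()
    for s in A:
        dist, preds = _bfs_dag(net, s)
        for t in B:
            if t == s:
                continue
            if t not in dist:
                result.no_path_pairs.append((s, t))
                continue
            chains, truncated = _node_chains(preds, s, t, max_paths_per_pair)
            if truncated:
                result.truncated_pairs.append((s, t))
                logger.warning(
                    "pair (%s, %s): more than %d minimal paths; truncated",
                    net.labels[s], net.labels[t], max_paths_per_pair,
                )
            chains.sort()
            for chain in chains:
                sign_options = [
                    sorted(net.signs(u, v), reverse=True)
                    for u, v in zip(chain, chain[1:])
                ]
                for combo in itertools.product(*sign_options):
                    mode = classify_path(combo)
                    if mode_filter != "both" and mode != mode_filter:
                        continue
                    result.paths.append(
                        RegulatoryPath(
                            source=s, target=t, nodes=chain,
                            labels=tuple(net.labels[i] for i in chain),
                            signs=tuple(combo), mode=mode,
                        )
                    )
    return result
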