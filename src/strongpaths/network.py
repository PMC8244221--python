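"""Confidence-weighted interaction networks.

The network file dialect is UTF-8, tab-separated, three columns, no header:
source label, target label, confidence score in (0,1] interpreted as the
probability that the interaction is real.  Duplicate edges are merged keeping
the maximum confidence and self-loops are dropped — a self-loop can never lie
on a simple source-to-target path and would inflate expansion scores.

Undirected edges are stored once under a canonical (min, max) index key and
traversed in both directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .annotation import AnnotationTable
from .errors import FormatError, InputError, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["ConfidenceNetwork", "parse_network", "induced_subgraph", "write_network"]


@dataclass
class ConfidenceNetwork:
    """A weighted (directed or undirected) graph with edge probabilities.

    ``labels`` indexes every node the network knows about; ``nodes`` is the
    active subset (an induced subgraph keeps the parent's index space so that
    node indices stay meaningful across subgraph extractions).
    """

    directed: bool
    labels: list[str]
    edges: dict[tuple[int, int], float] = field(default_factory=dict)
    nodes: frozenset[int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.nodes is None:
            self.nodes = frozenset(range(len(self.labels)))
        for (u, v), p in self.edges.items():
            if not 0.0 < p <= 1.0:
                raise ValidationError(f"edge ({u},{v}) confidence {p} not in (0,1]")
            if u == v:
                raise ValidationError(f"self-loop on node {u}")

    # -- basic accessors -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def label_of(self, index: int) -> str:
        return self.labels[index]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(label) from None

    def canonical(self, u: int, v: int) -> tuple[int, int]:
        """Canonical storage key for an edge."""
        if self.directed or u <= v:
            return (u, v)
        return (v, u)

    def confidence(self, u: int, v: int) -> float | None:
        return self.edges.get(self.canonical(u, v))

    def edge_list(self) -> list[tuple[int, int, float]]:
        return [(u, v, p) for (u, v), p in self.edges.items()]

    def adjacency(self) -> dict[int, list[tuple[int, float]]]:
        """Outgoing neighbor lists (symmetric when undirected)."""
        adj: dict[int, list[tuple[int, float]]] = {u: [] for u in self.nodes}
        for (u, v), p in self.edges.items():
            adj[u].append((v, p))
            if not self.directed:
                adj[v].append((u, p))
        return adj

    def incident(self, v: int) -> Iterator[tuple[int, float]]:
        """Every neighbor touching *v* regardless of direction (with p)."""
        for (a, b), p in self.edges.items():
            if a == v:
                yield b, p
            elif b == v:
                yield a, p

    def annotation(self) -> AnnotationTable:
        """A label-only annotation table over this network's nodes."""
        return AnnotationTable.from_labels(self.labels)


def parse_network(
    path: str | Path,
    table: AnnotationTable | None = None,
    directed: bool = False,
    score_divisor: float | None = None,
) -> ConfidenceNetwork:
    """Parse the three-column network dialect.

    When an annotation *table* is given, endpoints may use any identifier it
    knows and must resolve to exactly one node; node indices then coincide
    with annotation row numbers.  Without a table, labels are interned in
    order of first appearance.

    ``score_divisor`` rescales raw scores before validation (e.g. 1000 for
    combined scores exported on a 0-1000 scale).
    """
    if table is not None:
        labels = list(table.labels)
        intern: dict[str, int] | None = None
    else:
        labels = []
        intern = {}

    edges: dict[tuple[int, int], float] = {}
    n_self_loops = 0
    n_rows = 0

    def node_id(name: str, lineno: int) -> int:
        name = name.strip()
        if not name:
            raise FormatError(f"{path}: line {lineno}: empty node name")
        if table is not None:
            return table.resolve_unique(name, context=f"{path}: line {lineno}")
        assert intern is not None
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
                    f"{path}: line {lineno}: expected 3 tab-separated columns, "
                    f"got {len(cols)}"
                )
            try:
                p = float(cols[2])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: confidence {cols[2]!r} is not a number"
                ) from None
            if score_divisor is not None:
                p /= score_divisor
            if not 0.0 < p <= 1.0:
                raise ValidationError(
                    f"{path}: line {lineno}: confidence {p} outside (0, 1]"
                )
            u = node_id(cols[0], lineno)
            v = node_id(cols[1], lineno)
            n_rows += 1
            if u == v:
                n_self_loops += 1
                continue
            key = (u, v) if directed or u <= v else (v, u)
            prev = edges.get(key)
            if prev is None or p > prev:
                edges[key] = p

    if n_self_loops:
        logger.info("%s: dropped %d self-loop(s)", path, n_self_loops)
    return ConfidenceNetwork(directed=directed, labels=labels, edges=edges)


def induced_subgraph(net: ConfidenceNetwork, nodes: Iterable[int]) -> ConfidenceNetwork:
    """Subgraph on *nodes*: exactly the edges with both endpoints retained.

    The parent's label/index space is preserved, so the operation is
    idempotent and node indices remain comparable across calls.
    """
    keep = frozenset(nodes)
    unknown = keep - net.nodes
    if unknown:
        raise InputError(f"nodes not in network: {sorted(unknown)}")
    edges = {
        (u, v): p for (u, v), p in net.edges.items() if u in keep and v in keep
    }
    return ConfidenceNetwork(
        directed=net.directed, labels=net.labels, edges=edges, nodes=keep
    )


def _sorted_edges(net: ConfidenceNetwork) -> list[tuple[str, str, float]]:
    rows = []
    for (u, v), p in net.edges.items():
        a, b = net.labels[u], net.labels[v]
        if not net.directed and b < a:
            a, b = b, a
        rows.append((a, b, p))
    rows.sort()
    return rows


def write_network(
    net: ConfidenceNetwork, path: str | Path, format: str = "tsv"
) -> None:
    """Write *net* as the 3-column TSV dialect or Cytoscape SIF.

    TSV round-trips through :func:`parse_network` up to edge order and
    already-merged duplicates.  SIF uses interaction type ``pp``; confidences
    go to a sidecar ``<path>.attrs.tsv`` edge-attribute table, since SIF
    itself carries no weights.
    """
    path = Path(path)
    rows = _sorted_edges(net)
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            for a, b, p in rows:
                fh.write(f"{a}\t{b}\t{p!r}\n")
    elif format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for a, b, _ in rows:
                fh.write(f"{a} pp {b}\n")
        with open(f"{path}.attrs.tsv", "w", encoding="utf-8") as fh:
            fh.write("source\tinteraction\ttarget\tconfidence\n")
            for a, b, p in rows:
                fh.write(f"{a}\tpp\t{b}\t{p!r}\n")
    else:
        raise InputError(f"unknown output format {format!r}")
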