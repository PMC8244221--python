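"""Greedy confidence-weighted network expansion.

Given a current set of proteins, candidates outside the set are ranked by the
total confidence of their interactions *into* the set (candidate-candidate
edges do not count; for directed networks both orientations contribute — a
regulator and a target are both interaction partners).  Expansion adds the
top-n candidates, either in one batch ranking or sequentially with re-ranking
after every single addition, so edges to freshly added nodes start counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .errors import InputError
from .network import ConfidenceNetwork, induced_subgraph

logger = logging.getLogger(__name__)

__all__ = ["ExpansionResult", "extract_network", "rank_candidates", "expand"]


def extract_network(net: ConfidenceNetwork, genes: Iterable[int]) -> ConfidenceNetwork:
    """Induced subgraph on the input proteins; isolated inputs are retained.

    Input indices not present in the network are dropped with a warning; if
    none remain the call fails.
    """
    genes = set(genes)
    present = genes & net.nodes
    missing = genes - net.nodes
    if not present:
        raise InputError("no input gene is present in the background network")
    if missing:
        logger.warning(
            "%d input gene(s) absent from the background network: %s",
            len(missing), sorted(missing),
        )
    return induced_subgraph(net, present)


def rank_candidates(
    net: ConfidenceNetwork, current: Iterable[int]
) -> list[tuple[int, float]]:
    """Candidates outside *current* scored by Σ P(e) over edges into it.

    Sorted by score descending, then label ascending.  Nodes with no edge to
    the current set are omitted.
    """
    current = set(current)
    if not current:
        raise InputError("current node set is empty")
    scores: dict[int, float] = {}
    for (u, v), p in net.edges.items():
        if u in current and v not in current:
            scores[v] = scores.get(v, 0.0) + p
        elif v in current and u not in current:
            scores[u] = scores.get(u, 0.0) + p
    return sorted(scores.items(), key=lambda kv: (-kv[1], net.labels[kv[0]]))


@dataclass
class ExpansionResult:
    """Per-round additions plus the final induced network."""

    rounds: list[list[tuple[int, float]]] = field(default_factory=list)
    final_nodes: set[int] = field(default_factory=set)
    final_network: ConfidenceNetwork | None = None
    shortfall: bool = False  # fewer candidates existed than requested

    @property
    def added_nodes(self) -> list[int]:
        return [v for rnd in self.rounds for v, _ in rnd]


def expand(
    net: ConfidenceNetwork,
    current: Iterable[int],
    n: int,
    mode: str = "batch",
) -> ExpansionResult:
    """Grow *current* by the n highest-scoring external proteins.

    ``batch`` (default) takes the top n of a single ranking — one button
    press.  ``sequential`` re-ranks after each single addition, mimicking n
    repeated single-protein expansions.  If fewer than n candidates have any
    edge into the growing set, all of them are added and ``shortfall`` is
    flagged.
    """
    if n < 0:
        raise InputError(f"n must be >= 0, got {n}")
    if mode not in ("batch", "sequential"):
        raise InputError(f"mode must be 'batch' or 'sequential', got {mode!r}")
    nodes = set(current) & net.nodes
    if not nodes:
        raise InputError("no input gene is present in the background network")

    result = ExpansionResult()
    if n > 0 and mode == "batch":
        ranked = rank_candidates(net, nodes)[:n]
        if ranked:
            result.rounds.append(ranked)
            nodes |= {v for v, _ in ranked}
        result.shortfall = len(ranked) < n
    elif n > 0:
        for _ in range(n):
            ranked = rank_candidates(net, nodes)
            if not ranked:
                result.shortfall = True
                break
            result.rounds.append(ranked[:1])
            nodes.add(ranked[0][0])

    result.final_nodes = nodes
    result.final_network = induced_subgraph(net, nodes)
    return result
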