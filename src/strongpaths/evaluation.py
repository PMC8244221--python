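"""Benchmark statistics for path-search output against known pathway genes.

The question answered here: of the intermediate genes a search returned, how
many are already annotated members of the pathway, and is that overlap larger
than chance?  Significance is the upper-tail hypergeometric probability of
drawing at least the observed overlap when sampling ``found`` genes from a
background of N network nodes containing K pathway genes, with
Benjamini-Hochberg FDR correction across pathways.  Precision/recall compare
a found gene set against the curated pathway membership.

Conventions: the background population N is the node count of the network
actually searched; pathway sets are intersected with that background before K
is counted; sources and targets are excluded from both the found and pathway
sets before any statistic ("genes in the middle of the path").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .strongest_path import EpsilonSubnetwork, PathResult

__all__ = [
    "EnrichmentResult",
    "intermediate_genes",
    "hypergeom_pvalue",
    "fdr_adjust",
    "precision_recall",
    "enrich",
]


def intermediate_genes(
    result: PathResult | EpsilonSubnetwork,
    sources: Iterable[int],
    targets: Iterable[int],
) -> set[int]:
    """Nodes of a search result minus the query's sources and targets."""
    nodes = set(result.nodes)
    return nodes - set(sources) - set(targets)


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(population N, successes K, draws n).

    One-sided enrichment tail, inclusive of the observed overlap k — the
    ``phyper(k - 1, K, N - K, n, lower.tail = FALSE)`` convention.  Computed
    through scipy's log-gamma based survival function, numerically stable for
    genome-scale N.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise InputError(
            f"inconsistent counts: overlap={k}, found={n}, pathway={K}, "
            f"background={N}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def fdr_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    pvalues = list(pvalues)
    if not pvalues:
        return []
    if any(not 0.0 <= p <= 1.0 for p in pvalues):
        raise InputError(f"p-values must lie in [0, 1]: {pvalues}")
    _, adjusted, _, _ = multipletests(pvalues, method="fdr_bh")
    return [float(q) for q in adjusted]


def precision_recall(found: set, pathway: set) -> tuple[float, float]:
    """Fraction of found genes in the pathway / of pathway genes retrieved.

    Precision is defined as 0 for an empty found set (nothing retrieved).
    """
    if not pathway:
        raise InputError("pathway gene set is empty")
    overlap = len(found & pathway)
    precision = overlap / len(found) if found else 0.0
    recall = overlap / len(pathway)
    return precision, recall


@dataclass(frozen=True)
class EnrichmentResult:
    found: int                # intermediate genes returned by the search
    overlap: int              # of those, known pathway members
    pathway_in_background: int
    background_size: int
    p_value: float
    fdr: float | None = None  # filled in when adjusted across a batch
    precision: float = 0.0
    recall: float = 0.0


def enrich(
    found_genes: set,
    pathway_genes: set,
    background: set | int,
    sources: set | None = None,
    targets: set | None = None,
) -> EnrichmentResult:
    """Overlap counts, hypergeometric p, precision and recall for one pathway.

    *background* is either the searched network's node set (pathway genes are
    intersected with it before counting K) or a plain population size, in
    which case the pathway set is assumed pre-filtered.
    """
    exclude = set(sources or ()) | set(targets or ())
    found = set(found_genes) - exclude
    pathway = set(pathway_genes) - exclude
    if isinstance(background, int):
        N = background
    else:
        pool = set(background) - exclude
        pathway &= pool
        N = len(pool)
    if not pathway:
        raise InputError("no pathway gene lies in the background network")
    k = len(found & pathway)
    p = hypergeom_pvalue(k, len(found), len(pathway), N)
    prec, rec = precision_recall(found, pathway)
    return EnrichmentResult(
        found=len(found), overlap=k, pathway_in_background=len(pathway),
        background_size=N, p_value=p, precision=prec, recall=rec,
    )
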