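"""Node annotation tables: map arbitrary gene/protein identifiers to nodes.

The annotation file is a UTF-8 tab-separated file with no header.  Each row
describes one network node; column 1 is the canonical label, every further
column is a comma-separated list of alternative identifiers (gene symbols,
UniProt accessions, Ensembl IDs, ...).  Row order defines the 0-based node
index, which fixes deterministic tie-breaking everywhere downstream.

Identifier matching is case-insensitive and whitespace-trimmed; an identifier
shared by several nodes (e.g. an alias common to paralogs) resolves to all of
them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from .errors import FormatError, ResolutionError

logger = logging.getLogger(__name__)

__all__ = ["AnnotationRecord", "AnnotationTable", "parse_annotation"]


def _normalize(identifier: str) -> str:
    return identifier.strip().casefold()


@dataclass(frozen=True)
class AnnotationRecord:
    index: int
    label: str
    alt_ids: tuple[tuple[str, ...], ...]  # one tuple per extra column


@dataclass
class AnnotationTable:
    """Ordered node records plus a normalized-identifier lookup."""

    records: list[AnnotationRecord] = field(default_factory=list)
    lookup: dict[str, set[int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def resolve(self, query: str) -> set[int]:
        """All node indices whose label or any alternative identifier matches
        *query* (trimmed, case-folded).  Unknown identifiers yield the empty
        set; callers decide whether that is an error."""
        return set(self.lookup.get(_normalize(query), ()))

    def resolve_unique(self, query: str, context: str = "") -> int:
        """Resolve to exactly one node; ambiguity or absence is an error.

        Used for network-file endpoints, where a row must denote one node.
        """
        hits = self.resolve(query)
        where = f" ({context})" if context else ""
        if not hits:
            raise ResolutionError(f"unknown identifier {query!r}{where}")
        if len(hits) > 1:
            raise ResolutionError(
                f"ambiguous identifier {query!r}{where}: matches nodes "
                f"{sorted(hits)}"
            )
        return next(iter(hits))

    def resolve_list(
        self,
        queries: Iterable[str],
        on_missing: Literal["error", "warn"] = "error",
    ) -> tuple[set[int], list[str]]:
        """Union of :meth:`resolve` over *queries*.

        Returns ``(indices, unresolved)``.  Policy ``"error"`` aborts on the
        first unresolved query; ``"warn"`` logs and continues.  An entirely
        unresolved list is an error under either policy — an empty node set is
        never a valid source/target set downstream.
        """
        queries = list(queries)
        if not queries:
            raise ResolutionError("empty identifier list")
        found: set[int] = set()
        unresolved: list[str] = []
        for q in queries:
            hits = self.resolve(q)
            if hits:
                found |= hits
            else:
                if on_missing == "error":
                    raise ResolutionError(f"unknown identifier {q!r}")
                unresolved.append(q)
                logger.warning("identifier %r not found in annotation", q)
        if not found:
            raise ResolutionError(
                f"none of the {len(queries)} identifiers resolved"
            )
        return found, unresolved

    def _add(self, record: AnnotationRecord) -> None:
        self.records.append(record)
        ids = [record.label]
        for column in record.alt_ids:
            ids.extend(column)
        for ident in ids:
            key = _normalize(ident)
            if key:
                self.lookup.setdefault(key, set()).add(record.index)

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "AnnotationTable":
        """Build a trivial table from bare labels (no annotation file)."""
        table = cls()
        for i, label in enumerate(labels):
            table._add(AnnotationRecord(i, label, ()))
        return table


def parse_annotation(path: str | Path) -> AnnotationTable:
    """Parse the tab-separated annotation dialect described above.

    Raises :class:`FormatError` on an empty file or a row whose first column
    is empty (the canonical label is mandatory).
    """
    table = AnnotationTable()
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            cols = line.split("\t")
            label = cols[0].strip()
            if not label:
                raise FormatError(
                    f"{path}: line {lineno}: empty label in first column"
                )
            alt_ids = tuple(
                tuple(x.strip() for x in col.split(",") if x.strip())
                for col in cols[1:]
            )
            table._add(AnnotationRecord(n_rows, label, alt_ids))
            n_rows += 1
    if n_rows == 0:
        raise FormatError(f"{path}: annotation file has no records")
    return table
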