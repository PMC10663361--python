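"""Interval algebra on genomic coordinates.

All coordinates are 0-based half-open (BED convention). Two intervals
overlap iff they share at least one base; abutting intervals do not
overlap. Peak-to-TSS distance is measured from the nearest peak edge
(zero if the TSS falls inside the peak), which is the conservative
convention for calling elements "distal".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "GeneAnnotation",
    "UnassignableError",
    "overlaps",
    "find_overlaps",
    "distance_to_nearest_tss",
    "nearest_gene",
]

STRANDS = ("+", "-", ".")


class UnassignableError(ValueError):
    """Raised when a peak cannot be assigned to any gene (no gene on its
    chromosome)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open span ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int]:
        """Coordinate identity (chrom, start, end), ignoring strand."""
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene model: stable id, display symbol, TSS position and gene body."""

    gene_id: str
    symbol: str
    tss: int
    body: GenomicInterval
    strand: str = "+"
    is_tf: bool = False

    def __post_init__(self) -> None:
        if not (self.body.start <= self.tss <= self.body.end):
            raise ValueError(
                f"TSS {self.tss} of {self.gene_id} lies outside gene body "
                f"[{self.body.start}, {self.body.end}]"
            )


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff *a* and *b* share at least one base (half-open semantics)."""
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


def find_overlaps(
    queries: Sequence[GenomicInterval], subjects: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """All (query index, subject index) pairs whose intervals overlap.

    Pairs are returned sorted by query index then subject index. Subjects
    are grouped per chromosome and pre-sorted by start; for each query,
    candidates with ``start < query.end`` are located by binary search
    and then filtered on ``end > query.start``.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    chrom_groups: dict[str, list[int]] = {}
    for j, s in enumerate(subjects):
        chrom_groups.setdefault(s.chrom, []).append(j)
    for chrom, idx in chrom_groups.items():
        idx_arr = np.asarray(idx, dtype=np.int64)
        starts = np.asarray([subjects[j].start for j in idx], dtype=np.int64)
        ends = np.asarray([subjects[j].end for j in idx], dtype=np.int64)
        order = np.argsort(starts, kind="stable")
        by_chrom[chrom] = (starts[order], ends[order], idx_arr[order])

    pairs: list[tuple[int, int]] = []
    for i, q in enumerate(queries):
        grp = by_chrom.get(q.chrom)
        if grp is None:
            continue
        starts, ends, idx_arr = grp
        hi = int(np.searchsorted(starts, q.end, side="left"))
        if hi == 0:
            continue
        cand = np.nonzero(ends[:hi] > q.start)[0]
        pairs.extend((i, int(idx_arr[c])) for c in cand)
    pairs.sort()
    return pairs


def distance_to_nearest_tss(
    peak: GenomicInterval, genes: Iterable[GeneAnnotation]
) -> tuple[int, str]:
    """Distance in bp from the nearest peak edge to the nearest TSS.

    Returns ``(distance, gene_id)`` for the minimising gene. The distance
    is 0 when a TSS lies within ``[start, end)``; otherwise it is the
    minimum over genes of ``min(|tss - start|, |tss - (end - 1)|)``.
    Ties are broken by lexicographically smallest gene_id.
    """
    best: tuple[int, str] | None = None
    for g in genes:
        if g.body.chrom != peak.chrom:
            continue
        if peak.start <= g.tss < peak.end:
            d = 0
        else:
            d = min(abs(g.tss - peak.start), abs(g.tss - (peak.end - 1)))
        cand = (d, g.gene_id)
        if best is None or cand < best:
            best = cand
    if best is None:
        raise UnassignableError(f"no gene on chromosome {peak.chrom}")
    return best


def nearest_gene(peak: GenomicInterval, genes: Iterable[GeneAnnotation]) -> str:
    """gene_id of the gene whose TSS is nearest to *peak* (ties: smallest id)."""
    return distance_to_nearest_tss(peak, genes)[1]
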