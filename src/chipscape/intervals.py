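"""Genomic coordinate primitives.

All coordinates are 0-based half-open internally (BED convention); VCF
positions are converted on I/O.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from intervaltree import IntervalTree


@dataclass(frozen=True)
class GenomicInterval:
    """A chrom + 0-based half-open span, optionally stranded and named."""

    chrom: str
    start: int
    end: int
    strand: Optional[str] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def build_trees(intervals: Iterable[GenomicInterval]) -> dict:
    """Index intervals per chromosome for overlap queries."""
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def query_overlaps(trees: dict, chrom: str, start: int, end: int) -> list:
    tree = trees.get(chrom)
    if tree is None:
        return []
    return [hit.data for hit in tree.overlap(start, end)]
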