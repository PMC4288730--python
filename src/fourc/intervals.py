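"""Genomic intervals, 0-based half-open.

All internal coordinates are 0-based half-open (BED convention). Conversion
from 1-based inclusive coordinates (the convention of genome browsers and of
most published locus coordinates) happens only at I/O boundaries, via
:func:`from_one_based`.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end}): need 0 <= start < end")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(self.chrom, max(self.start, other.start), min(self.end, other.end))

    def union_span(self, other: "GenomicInterval") -> "GenomicInterval":
        """Smallest interval covering both (they need not touch)."""
        if self.chrom != other.chrom:
            raise ValueError("cannot span intervals on different chromosomes")
        return GenomicInterval(self.chrom, min(self.start, other.start), max(self.end, other.end))

    def jaccard(self, other: "GenomicInterval") -> float:
        inter = self.intersect(other)
        inter_len = inter.length if inter else 0
        union_len = self.length + other.length - inter_len
        return inter_len / union_len if union_len else 0.0

    def __str__(self) -> str:  # browser-style, 1-based inclusive
        return f"{self.chrom}:{self.start + 1}-{self.end}"


def from_one_based(chrom: str, start: int, end: int, strand: str = ".") -> GenomicInterval:
    """Build an interval from 1-based inclusive coordinates (e.g. ``chr2:172551998-172555000``)."""
    return GenomicInterval(chrom, start - 1, end, strand)


def jaccard(a: GenomicInterval, b: GenomicInterval) -> float:
    return a.jaccard(b)
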