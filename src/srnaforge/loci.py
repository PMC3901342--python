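"""Genomic coordinate primitives.

All coordinates in this package are 1-based and inclusive on both ends,
matching the locus strings reported throughout the result tables
(``Chr4:104560738-104560800+``).  Conversion to BED's 0-based half-open
convention happens only at the BED writer (start - 1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_LOCUS_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)(?P<strand>[+-])$")


@dataclass(frozen=True, order=True)
class GenomicLocus:
    """A strand-aware interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval {self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}{self.strand}"

    @classmethod
    def parse(cls, s: str) -> "GenomicLocus":
        m = _LOCUS_RE.match(s)
        if m is None:
            raise ValueError(f"cannot parse locus string {s!r}")
        return cls(m["chrom"], int(m["start"]), int(m["end"]), m["strand"])

    def overlap(self, other: "GenomicLocus") -> int:
        """Number of overlapping bases (strand-agnostic); 0 if disjoint."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def reciprocal_overlap(self, other: "GenomicLocus") -> float:
        """min(overlap/len(self), overlap/len(other))."""
        ov = self.overlap(other)
        if ov == 0:
            return 0.0
        return min(ov / self.length, ov / other.length)

    def contains(self, other: "GenomicLocus") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


_COMP = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet; U treated as T)."""
    return seq.translate(_COMP)[::-1]
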