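"""End-tolerant exact mapping of collapsed tags to the genome.

Tags map to every genomic locus where the read core (all positions except
the two outermost at each end) matches exactly and at most two mismatches
fall within those outermost positions.  Both strands are searched; loci are
reported 1-based inclusive.  Tags hitting more loci than ``max_loci`` are
flagged as repeat-derived and excluded from discovery.

The implementation seeds with an exact 11-mer from the core (the shortest
core, for a 15-nt tag, is 11 nt) against a sorted k-mer index per
chromosome, then verifies the full tag under the end-mismatch rule; the
output contract is identical to a brute-force scan of every position on
both strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .loci import GenomicLocus, revcomp
from .preprocess import UniqueTag

SEED_K = 11
_CODES = np.full(256, 4, dtype=np.int64)
for _i, _c in enumerate("ACGT"):
    _CODES[ord(_c)] = _i

__all__ = ["Hit", "TagAlignment", "GenomeIndex", "align_tag", "count_loci"]


@dataclass(frozen=True)
class Hit:
    tag: str  # tag sequence (read orientation)
    locus: GenomicLocus
    mismatch_positions: tuple[int, ...]  # 0-based offsets from the read 5' end


@dataclass
class TagAlignment:
    tag: UniqueTag
    hits: list[Hit] = field(default_factory=list)
    repeat: bool = False  # more than max_loci qualifying loci

    @property
    def n_loci(self) -> int:
        return len(self.hits)


class GenomeIndex:
    """Sorted 11-mer index over the forward strand of each chromosome."""

    def __init__(self, genome: dict[str, str]):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self._kmers: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        powers = 4 ** np.arange(SEED_K - 1, -1, -1, dtype=np.int64)
        for chrom, seq in self.genome.items():
            codes = _CODES[np.frombuffer(seq.encode(), dtype=np.uint8)]
            if len(codes) < SEED_K:
                self._kmers[chrom] = (np.empty(0, np.int64), np.empty(0, np.int64))
                continue
            windows = np.lib.stride_tricks.sliding_window_view(codes, SEED_K)
            # k-mers containing non-ACGT get codes >= 4**SEED_K and never match
            kmers = windows @ powers
            order = np.argsort(kmers, kind="stable")
            self._kmers[chrom] = (kmers[order], order)

    def seed_positions(self, chrom: str, seed: str) -> np.ndarray:
        """0-based start positions of exact occurrences of an 11-mer."""
        codes = _CODES[np.frombuffer(seed.encode(), dtype=np.uint8)]
        if (codes >= 4).any():
            return np.empty(0, np.int64)
        key = int(codes @ (4 ** np.arange(SEED_K - 1, -1, -1, dtype=np.int64)))
        sk, order = self._kmers[chrom]
        lo = np.searchsorted(sk, key, side="left")
        hi = np.searchsorted(sk, key, side="right")
        return np.sort(order[lo:hi])


def _verify(genome_seq: str, p: int, s: str, end_positions: frozenset,
            max_mm: int) -> tuple[int, ...] | None:
    """Mismatch offsets of s vs genome at p, or None if the rule fails."""
    L = len(s)
    if p < 0 or p + L > len(genome_seq):
        return None
    mism = []
    ref = genome_seq[p : p + L]
    for off in range(L):
        if ref[off] != s[off]:
            if off not in end_positions or len(mism) >= max_mm:
                return None
            mism.append(off)
    return tuple(mism)


def align_tag(
    tag: UniqueTag,
    index: GenomeIndex,
    max_end_mismatches: int = 2,
    max_loci: int = 20,
) -> TagAlignment:
    """All genomic loci of a tag under the end-mismatch rule.

    Mismatches are confined to read offsets {0, 1, L-2, L-1}; up to
    *max_end_mismatches* in total (both may sit at one end).  Minus-strand
    hits report mismatch offsets from the read's own 5' end.
    """
    seq = tag.sequence.upper()
    L = len(seq)
    end_pos = frozenset({0, 1, L - 2, L - 1})
    hits: list[Hit] = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else revcomp(seq)
        seed = s[2 : 2 + SEED_K]  # inside the exact core
        for chrom, gseq in index.genome.items():
            for p_core in map(int, index.seed_positions(chrom, seed)):
                p = p_core - 2
                mism = _verify(gseq, p, s, end_pos, max_end_mismatches)
                if mism is None:
                    continue
                if strand == "-":
                    mism = tuple(sorted(L - 1 - q for q in mism))
                hits.append(
                    Hit(seq, GenomicLocus(chrom, p + 1, p + L, strand), mism)
                )
    hits.sort(key=lambda h: (h.locus.chrom, h.locus.start, h.locus.strand))
    if len(hits) > max_loci:
        return TagAlignment(tag, [], repeat=True)
    return TagAlignment(tag, hits)


def count_loci(alignments: list[TagAlignment]) -> pd.DataFrame:
    """Per-tag locus counts plus the multi-copy report.

    Columns: tag, n_loci, repeat.  Tags flagged repeat carry their reason in
    the ``excluded_reason`` column.
    """
    rows = [
        {
            "tag": a.tag.sequence,
            "n_loci": a.n_loci,
            "repeat": a.repeat,
            "excluded_reason": "repeat" if a.repeat else "",
        }
        for a in alignments
    ]
    return pd.DataFrame(rows, columns=["tag", "n_loci", "repeat", "excluded_reason"])
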