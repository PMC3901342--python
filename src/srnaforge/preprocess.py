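"""Read cleaning: adapter trimming, quality/length gates, tag collapsing.

Raw reads carry the 3' sequencing adapter after the small-RNA insert.
Trimming finds the best adapter-prefix match (longest wins, leftmost on
ties); reads whose mean Phred falls below a floor are dropped; surviving
inserts are restricted to the 15-35 nt retention window and collapsed into
unique tags with per-library counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

MIN_LEN = 15
MAX_LEN = 35

__all__ = [
    "UniqueTag",
    "TrimResult",
    "CollapseStats",
    "trim_adapter",
    "filter_and_collapse",
    "collapse_libraries",
    "summarize_length_distribution",
    "read_sequences",
]


@dataclass(frozen=True)
class UniqueTag:
    """A collapsed read sequence with per-library counts."""

    sequence: str
    count_f3: int = 0
    count_f4: int = 0

    @property
    def total(self) -> int:
        return self.count_f3 + self.count_f4


@dataclass(frozen=True)
class TrimResult:
    insert: str
    trimmed: bool  # False when no adapter match of sufficient overlap


def trim_adapter(
    read: str,
    adapter: str,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
) -> TrimResult | None:
    """Remove a 3' adapter by prefix matching.

    Scans every position where a prefix of *adapter* could start; a match
    needs at least *min_overlap* aligned bases with a mismatch fraction of
    at most *max_mismatch_rate*.  The longest match wins; among equal
    lengths the leftmost wins, so the scan proceeds left to right and the
    first qualifying position is returned.  Without any match the read is
    returned unchanged and flagged untrimmed.  Empty reads yield None.
    """
    if not read:
        return None
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    read_u = read.upper()
    adapter_u = adapter.upper()
    for i in range(0, len(read_u) - min_overlap + 1):
        overlap = min(len(adapter_u), len(read_u) - i)
        allowed = int(max_mismatch_rate * overlap)
        mism = 0
        for a, b in zip(read_u[i : i + overlap], adapter_u):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        else:
            return TrimResult(read_u[:i], True)
    return TrimResult(read_u, False)


@dataclass
class CollapseStats:
    n_input: int = 0
    n_too_short: int = 0
    n_too_long: int = 0
    n_non_acgt: int = 0
    n_retained: int = 0
    discarded_by_reason: dict = field(default_factory=dict)

    def finalize(self) -> "CollapseStats":
        self.discarded_by_reason = {
            "too_short": self.n_too_short,
            "too_long": self.n_too_long,
            "non_acgt": self.n_non_acgt,
        }
        return self


def filter_and_collapse(
    inserts: Iterable[str],
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
) -> tuple[Counter, CollapseStats]:
    """Collapse one library's inserts into sequence counts.

    Inserts outside [min_len, max_len] or containing characters other than
    ACGT are discarded; identical sequences are merged.
    """
    counts: Counter = Counter()
    stats = CollapseStats()
    acgt = set("ACGT")
    for ins in inserts:
        stats.n_input += 1
        seq = ins.upper()
        if len(seq) < min_len:
            stats.n_too_short += 1
        elif len(seq) > max_len:
            stats.n_too_long += 1
        elif not acgt.issuperset(seq):
            stats.n_non_acgt += 1
        else:
            counts[seq] += 1
            stats.n_retained += 1
    return counts, stats.finalize()


def collapse_libraries(
    inserts_f3: Iterable[str],
    inserts_f4: Iterable[str],
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
) -> tuple[list[UniqueTag], dict[str, CollapseStats]]:
    """Collapse both libraries into one unique-tag set with paired counts."""
    c3, s3 = filter_and_collapse(inserts_f3, min_len, max_len)
    c4, s4 = filter_and_collapse(inserts_f4, min_len, max_len)
    tags = [
        UniqueTag(seq, c3.get(seq, 0), c4.get(seq, 0))
        for seq in sorted(set(c3) | set(c4))
    ]
    return tags, {"F3": s3, "F4": s4}


def summarize_length_distribution(
    tags: Iterable[UniqueTag],
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
) -> pd.DataFrame:
    """Read counts by insert length and library, with 21-24 nt fractions.

    Returns a DataFrame indexed by length with columns F3/F4 (read counts,
    weighted by tag counts) and frac_F3/frac_F4.  The 21-24 nt window is
    where canonical Dicer products concentrate; its summed fraction is
    stored in ``df.attrs["frac_21_24"]``.
    """
    idx = range(min_len, max_len + 1)
    df = pd.DataFrame(0, index=pd.Index(idx, name="length"), columns=["F3", "F4"])
    for t in tags:
        L = len(t.sequence)
        if L in df.index:
            df.loc[L, "F3"] += t.count_f3
            df.loc[L, "F4"] += t.count_f4
    totals = df.sum()
    for lib in ("F3", "F4"):
        df[f"frac_{lib}"] = df[lib] / totals[lib] if totals[lib] > 0 else 0.0
    window = df.loc[21:24]
    df.attrs["frac_21_24"] = {
        lib: (window[lib].sum() / totals[lib]) if totals[lib] > 0 else 0.0
        for lib in ("F3", "F4")
    }
    return df


def read_sequences(
    path: str, min_mean_phred: float = 20.0
) -> Iterator[str]:
    """Yield read sequences from FASTQ or FASTA, applying the quality gate.

    FASTQ reads whose mean Phred score is below *min_mean_phred* are
    dropped; FASTA input has no qualities and passes through.
    """
    fmt = "fastq" if str(path).endswith(("fastq", "fq")) else "fasta"
    for rec in SeqIO.parse(path, fmt):
        if fmt == "fastq":
            quals = rec.letter_annotations["phred_quality"]
            if quals and sum(quals) / len(quals) < min_mean_phred:
                continue
        yield str(rec.seq)
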