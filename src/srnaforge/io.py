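"""Readers and writers for the standard formats the pipeline touches."""

from __future__ import annotations

from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO

from .loci import GenomicLocus

__all__ = [
    "read_genome",
    "read_fasta_dict",
    "read_gff3_features",
    "write_tags_fasta",
    "write_tsv",
    "read_tsv",
    "write_bed6",
]


def read_genome(path: str | Path) -> dict[str, str]:
    """Chromosome name -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_fasta_dict(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gff3_features(path: str | Path) -> list[tuple[GenomicLocus, str, str]]:
    """All features as (locus, type, Name attribute) tuples."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    out = []
    for feat in db.all_features():
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        name = feat.attributes.get("Name", [feat.id])[0]
        out.append((GenomicLocus(feat.seqid, feat.start, feat.end, strand),
                    feat.featuretype, name))
    return out


def write_tags_fasta(tags, path: str | Path) -> None:
    """Collapsed tags as ``>tag{n}_x{count}`` FASTA records."""
    with open(path, "w") as fh:
        for n, t in enumerate(tags, 1):
            fh.write(f">tag{n}_x{t.total}\n{t.sequence}\n")


def write_tsv(df: pd.DataFrame, path: str | Path, config_hash: str = "") -> None:
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# srnaforge-config-hash: {config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_bed6(loci: list[tuple[str, GenomicLocus]], path: str | Path) -> None:
    """BED6 output; BED is 0-based half-open, so start is shifted by -1."""
    with open(path, "w") as fh:
        for name, loc in loci:
            fh.write(
                f"{loc.chrom}\t{loc.start - 1}\t{loc.end}\t{name}\t0\t{loc.strand}\n"
            )
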