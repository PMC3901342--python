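"""Novel miRNA gene calling, conservation classes, clusters, mirtrons.

Passing hairpin candidates become miRNA genes: candidates overlapping a
known precursor merge into the known gene; the rest are deduplicated by
locus (>= 50% reciprocal overlap) and identical mature sequences across
loci merge into one multi-locus gene.  Novel genes split into conserved
(mature within a small substitution distance of an ortholog mature from
another species) and species-specific classes, and are named per library
and class — e.g. ``ssc-miR-F3-C1`` (conserved) or ``ssc-miR-F4-S12``
(specific) — with counters assigned in genomic order.  Genes within 10 kb
of each other form clusters; precursors coinciding with a whole annotated
intron are flagged as mirtrons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .hairpin import HairpinCandidate
from .loci import GenomicLocus

CLUSTER_WINDOW = 10_000
CONSERVATION_MAX_SUBS = 2
MIRTRON_TOLERANCE = 3

__all__ = [
    "MirnaGene",
    "call_novel",
    "classify_conservation",
    "name_genes",
    "detect_clusters",
    "detect_mirtrons",
    "genomic_density",
]


@dataclass
class MirnaGene:
    gene_id: str
    name: str
    loci: list[GenomicLocus]
    mature_sequence: str
    star_sequence: str | None
    status: str  # known | conserved_novel | specific_novel
    mirtron: bool = False
    cluster_id: str | None = None
    intergenic: bool = False
    present_f3: bool = False
    present_f4: bool = False
    candidates: list[HairpinCandidate] = field(default_factory=list)

    @property
    def primary_locus(self) -> GenomicLocus:
        return self.loci[0]


def _mature_seq(cand: HairpinCandidate) -> str:
    m0, m1 = cand.mature_span
    return cand.fold.sequence[m0 : m1 + 1].replace("U", "T")


def _star_seq(cand: HairpinCandidate) -> str | None:
    if cand.star_span is None:
        return None
    s0, s1 = cand.star_span
    return cand.fold.sequence[s0 : s1 + 1].replace("U", "T")


def call_novel(
    candidates: list[HairpinCandidate],
    known_pre_loci: dict[str, GenomicLocus | list[GenomicLocus]] | None = None,
    min_reciprocal_overlap: float = 0.5,
) -> tuple[list[MirnaGene], dict[str, str]]:
    """Group passing candidates into genes, separating known from novel.

    Returns the gene list (known genes first, then novel in genomic order)
    and a map from each candidate's precursor locus string to its gene id.
    Candidates overlapping a known precursor merge into that gene; novel
    candidates merge when their precursor loci reciprocally overlap >= 50%
    or their mature sequences are identical (multi-copy loci count as one
    gene).
    """
    known: dict[str, list[GenomicLocus]] = {
        kid: (loci if isinstance(loci, list) else [loci])
        for kid, loci in (known_pre_loci or {}).items()
    }
    passing = [c for c in candidates if c.pass_rules and c.precursor_locus]
    locus_to_gene: dict[str, str] = {}
    genes: dict[str, MirnaGene] = {}

    novel: list[HairpinCandidate] = []
    for cand in passing:
        hit_known = None
        for kid, klocs in known.items():
            if any(
                kloc.chrom == cand.precursor_locus.chrom
                and kloc.strand == cand.precursor_locus.strand
                and kloc.overlap(cand.precursor_locus) > 0
                for kloc in klocs
            ):
                hit_known = kid
                break
        if hit_known is not None:
            g = genes.setdefault(
                hit_known,
                MirnaGene(
                    gene_id=hit_known,
                    name=hit_known,
                    loci=list(known[hit_known]),
                    mature_sequence=_mature_seq(cand),
                    star_sequence=_star_seq(cand),
                    status="known",
                ),
            )
            g.candidates.append(cand)
            locus_to_gene[str(cand.precursor_locus)] = hit_known
        else:
            novel.append(cand)

    # deduplicate novel candidates: locus overlap first, then identical mature
    novel.sort(key=lambda c: (c.precursor_locus.chrom, c.precursor_locus.start))
    groups: list[list[HairpinCandidate]] = []
    for cand in novel:
        placed = False
        for grp in groups:
            if any(
                cand.precursor_locus.reciprocal_overlap(o.precursor_locus)
                >= min_reciprocal_overlap
                and cand.precursor_locus.strand == o.precursor_locus.strand
                for o in grp
            ):
                grp.append(cand)
                placed = True
                break
        if not placed:
            groups.append([cand])
    # merge groups sharing an identical mature sequence (multi-copy loci)
    by_mature: dict[str, list[list[HairpinCandidate]]] = {}
    for grp in groups:
        by_mature.setdefault(_mature_seq(grp[0]), []).append(grp)
    n = 0
    for mature, grps in sorted(
        by_mature.items(),
        key=lambda kv: (
            kv[1][0][0].precursor_locus.chrom,
            kv[1][0][0].precursor_locus.start,
        ),
    ):
        n += 1
        gid = f"novel-{n}"
        all_cands = [c for grp in grps for c in grp]
        loci = []
        for grp in grps:
            best = min(grp, key=lambda c: c.fold.delta_g)
            loci.append(best.precursor_locus)
        genes[gid] = MirnaGene(
            gene_id=gid,
            name=gid,
            loci=loci,
            mature_sequence=mature,
            star_sequence=_star_seq(all_cands[0]),
            status="novel",
            candidates=all_cands,
        )
        for c in all_cands:
            locus_to_gene[str(c.precursor_locus)] = gid

    ordered = [g for g in genes.values() if g.status == "known"] + [
        g for g in genes.values() if g.status != "known"
    ]
    return ordered, locus_to_gene


def classify_conservation(
    mature: str,
    ortholog_matures: list[str],
    max_subs: int = CONSERVATION_MAX_SUBS,
) -> str:
    """conserved_novel vs specific_novel by distance to ortholog matures.

    Conserved when the mature is within *max_subs* substitutions of an
    equal-length ortholog, or within *max_subs* mismatches of an ortholog
    differing by a single end extension (length difference <= max_subs,
    anchored at either end).
    """
    m = mature.upper().replace("U", "T")
    for orth in ortholog_matures:
        o = orth.upper().replace("U", "T")
        if len(o) == len(m):
            if sum(a != b for a, b in zip(m, o)) <= max_subs:
                return "conserved_novel"
        elif abs(len(o) - len(m)) <= max_subs:
            short, long_ = (m, o) if len(m) < len(o) else (o, m)
            for anchored in (long_[: len(short)], long_[-len(short) :]):
                if sum(a != b for a, b in zip(short, anchored)) <= max_subs:
                    return "conserved_novel"
    return "specific_novel"


def name_genes(
    genes: list[MirnaGene],
    ortholog_matures: list[str],
    library: str,
    max_subs: int = CONSERVATION_MAX_SUBS,
    prefix: str = "ssc-miR",
) -> None:
    """Classify and name novel genes in place, in genomic order.

    Conserved novels get ``{prefix}-{library}-C{n}``, specific novels
    ``{prefix}-{library}-S{n}``; counters run per class in genomic order.
    """
    c = s = 0
    for g in sorted(
        (g for g in genes if g.status != "known"),
        key=lambda g: (g.primary_locus.chrom, g.primary_locus.start),
    ):
        g.status = classify_conservation(g.mature_sequence, ortholog_matures, max_subs)
        if g.status == "conserved_novel":
            c += 1
            g.name = f"{prefix}-{library}-C{c}"
        else:
            s += 1
            g.name = f"{prefix}-{library}-S{s}"


def detect_clusters(
    loci: list[tuple[str, GenomicLocus]],
    window: int = CLUSTER_WINDOW,
) -> tuple[dict[str, str], dict[str, list[GenomicLocus]]]:
    """Chain precursors within *window* bp into clusters.

    *loci* is a list of (gene_id, precursor locus).  Adjacent precursors on
    one chromosome chain while the gap (next.start - prev.end) is strictly
    below *window*, strand ignored; maximal chains of >= 2 become clusters.
    Returns (gene_id -> cluster_id for clustered genes, cluster_id -> the
    chained loci).  A multi-copy gene joins a cluster through whichever of
    its loci sits in the chain.
    """
    by_chrom: dict[str, list[tuple[str, GenomicLocus]]] = {}
    for gid, loc in loci:
        by_chrom.setdefault(loc.chrom, []).append((gid, loc))
    out: dict[str, str] = {}
    cluster_loci: dict[str, list[GenomicLocus]] = {}
    n_cluster = 0
    for chrom in sorted(by_chrom):
        entries = sorted(by_chrom[chrom], key=lambda e: (e[1].start, e[1].end))
        chain: list[tuple[str, GenomicLocus]] = [entries[0]]
        prev_end = entries[0][1].end
        chains: list[list[tuple[str, GenomicLocus]]] = []
        for gid, loc in entries[1:]:
            if loc.start - prev_end < window:
                chain.append((gid, loc))
                prev_end = max(prev_end, loc.end)
            else:
                chains.append(chain)
                chain = [(gid, loc)]
                prev_end = loc.end
        chains.append(chain)
        for ch in chains:
            uniq = list(dict.fromkeys(gid for gid, _ in ch))
            if len(ch) >= 2 and len(uniq) >= 2:
                n_cluster += 1
                cid = f"cluster-{n_cluster}"
                for gid in uniq:
                    out[gid] = cid
                cluster_loci[cid] = [loc for _, loc in ch]
    return out, cluster_loci


def detect_mirtrons(
    loci: list[tuple[str, GenomicLocus]],
    introns: list[GenomicLocus],
    tolerance: int = MIRTRON_TOLERANCE,
) -> dict[str, bool]:
    """Flag precursors whose both ends match one intron's splice boundaries.

    A precursor is a mirtron when its start lies within *tolerance* nt of
    the donor boundary and its end within *tolerance* of the acceptor
    boundary of a single annotated intron on the same strand.  With no
    intron annotation every flag is False.
    """
    flags: dict[str, bool] = {}
    for gid, loc in loci:
        hit = any(
            intr.chrom == loc.chrom
            and intr.strand == loc.strand
            and abs(loc.start - intr.start) <= tolerance
            and abs(loc.end - intr.end) <= tolerance
            for intr in introns
        )
        flags[gid] = flags.get(gid, False) or hit
    return flags


def genomic_density(
    loci: list[GenomicLocus],
    chrom_lengths: dict[str, int],
) -> pd.DataFrame:
    """Precursors per Mb for each chromosome, rounded to 2 decimals."""
    for chrom, ln in chrom_lengths.items():
        if ln <= 0:
            raise ValueError(f"zero-length chromosome {chrom}")
    counts = {c: 0 for c in chrom_lengths}
    for loc in loci:
        if loc.chrom in counts:
            counts[loc.chrom] += 1
    rows = [
        {
            "chrom": c,
            "n_loci": counts[c],
            "length_bp": chrom_lengths[c],
            "density_per_mb": round(counts[c] / (chrom_lengths[c] / 1e6), 2),
        }
        for c in sorted(chrom_lengths)
    ]
    return pd.DataFrame(rows)
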