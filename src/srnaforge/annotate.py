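"""Tag classification, known-miRNA assignment, and isomiR cataloguing.

Tags are classified against the annotation hierarchy with a fixed priority:
known mature miRNA first (so genuine miRNA reads are never lost to an
overlapping annotation), then rRNA > tRNA > snoRNA > other ncRNA > mRNA
exon; mapped tags matching nothing are miRNA candidates.  Tags assigned to
a known (or discovered) product are recorded as isomiRs — variants of the
reference mature sequence differing by 5'/3' end offsets or non-templated
3' additions — and the reference isomiR of each product is the variant
with the highest read count, which need not equal the database sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .align import TagAlignment
from .loci import GenomicLocus

CATEGORY_PRIORITY = ["rRNA", "tRNA", "snoRNA", "other_ncRNA", "mRNA"]
CATEGORIES = ["known_mirna"] + CATEGORY_PRIORITY + ["candidate", "unmapped", "repeat"]

#: GFF3 feature types mapped to classification categories
FEATURE_CATEGORY = {
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "snoRNA": "snoRNA",
    "snRNA": "other_ncRNA",
    "ncRNA": "other_ncRNA",
    "exon": "mRNA",
}

OFFSET5_BOUNDS = (-4, 4)
OFFSET3_BOUNDS = (-6, 6)
NTA_MAX = 3

__all__ = [
    "AnnotationSet",
    "KnownProduct",
    "classify_tag",
    "classify_tags",
    "assign_known",
    "catalog_isomirs",
]


class AnnotationSet:
    """Interval lookup over annotation features, per chromosome."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    def add(self, locus: GenomicLocus, ftype: str, name: str = "") -> None:
        tree = self._trees.setdefault(locus.chrom, IntervalTree())
        # store half-open [start, end+1) so 1-bp features are representable
        tree.addi(locus.start, locus.end + 1, (ftype, locus.strand, name))

    @classmethod
    def from_features(
        cls, features: list[tuple[GenomicLocus, str, str]]
    ) -> "AnnotationSet":
        out = cls()
        for locus, ftype, name in features:
            out.add(locus, ftype, name)
        return out

    def overlapping(self, locus: GenomicLocus) -> list[tuple[int, str, str, str]]:
        """(overlap_bp, feature_type, strand, name) for features hit."""
        tree = self._trees.get(locus.chrom)
        if tree is None:
            return []
        out = []
        for iv in tree.overlap(locus.start, locus.end + 1):
            ov = min(iv.end - 1, locus.end) - max(iv.begin, locus.start) + 1
            ftype, strand, name = iv.data
            out.append((ov, ftype, strand, name))
        return out


def classify_tag(
    alignment: TagAlignment,
    annotation: AnnotationSet,
    min_mirna_overlap: int = 16,
) -> str:
    """One category per tag under the fixed priority order."""
    if alignment.repeat:
        return "repeat"
    if not alignment.hits:
        return "unmapped"
    found: set[str] = set()
    for hit in alignment.hits:
        for ov, ftype, strand, _name in annotation.overlapping(hit.locus):
            if ftype == "miRNA" and strand == hit.locus.strand and ov >= min_mirna_overlap:
                return "known_mirna"
            cat = FEATURE_CATEGORY.get(ftype)
            if cat is not None:
                found.add(cat)
    for cat in CATEGORY_PRIORITY:
        if cat in found:
            return cat
    return "candidate"


def classify_tags(
    alignments: list[TagAlignment],
    annotation: AnnotationSet,
    min_mirna_overlap: int = 16,
) -> pd.DataFrame:
    rows = [
        {
            "tag": a.tag.sequence,
            "category": classify_tag(a, annotation, min_mirna_overlap),
            "count_f3": a.tag.count_f3,
            "count_f4": a.tag.count_f4,
        }
        for a in alignments
    ]
    return pd.DataFrame(rows, columns=["tag", "category", "count_f3", "count_f4"])


@dataclass(frozen=True)
class KnownProduct:
    """A quantifiable mature or star species anchored at a genomic locus."""

    product_id: str  # "{gene_id}|mature" or "{gene_id}|star"
    locus: GenomicLocus


def _end_offsets(hit_locus: GenomicLocus, prod: GenomicLocus) -> tuple[int, int]:
    """5'/3' end offsets of the tag relative to the product, transcript sense."""
    if prod.strand == "+":
        return hit_locus.start - prod.start, hit_locus.end - prod.end
    return prod.end - hit_locus.end, prod.start - hit_locus.start


def _nta_suffix(hit) -> str:
    """Non-templated 3' tail: trailing A/T mismatches at the read 3' end."""
    L = len(hit.tag)
    tail = []
    mism = set(hit.mismatch_positions)
    for off in (L - 1, L - 2, L - 3):
        if off in mism and hit.tag[off] in "AT":
            tail.append(hit.tag[off])
        else:
            break
    return "".join(reversed(tail))


def assign_known(
    alignments: list[TagAlignment],
    products: list[KnownProduct],
    offset5_bounds: tuple[int, int] = OFFSET5_BOUNDS,
    offset3_bounds: tuple[int, int] = OFFSET3_BOUNDS,
) -> pd.DataFrame:
    """Assign tags to the products whose loci they overlap, as isomiRs.

    A tag is assigned to the same-strand product its hit overlaps with end
    offsets inside the isomiR bounds (the non-templated tail is excluded
    from the 3' offset first).  Ambiguity is resolved by largest overlap,
    then lowest product id.  Returns one row per (product, sequence):
    product_id, sequence, offset5, offset3, nta, count_f3, count_f4.
    """
    trees: dict[str, IntervalTree] = {}
    by_id = {p.product_id: p for p in products}
    for p in products:
        trees.setdefault(p.locus.chrom, IntervalTree()).addi(
            p.locus.start, p.locus.end + 1, p.product_id
        )
    rows: dict[tuple[str, str], dict] = {}
    for aln in alignments:
        if aln.repeat or not aln.hits:
            continue
        best = None  # (overlap, product_id, hit, off5, off3, nta)
        for hit in aln.hits:
            tree = trees.get(hit.locus.chrom)
            if tree is None:
                continue
            for iv in tree.overlap(hit.locus.start, hit.locus.end + 1):
                prod = by_id[iv.data]
                if prod.locus.strand != hit.locus.strand:
                    continue
                nta = _nta_suffix(hit)
                off5, off3 = _end_offsets(hit.locus, prod.locus)
                off3 -= len(nta)
                if not (offset5_bounds[0] <= off5 <= offset5_bounds[1]):
                    continue
                if not (offset3_bounds[0] <= off3 <= offset3_bounds[1]):
                    continue
                ov = prod.locus.overlap(hit.locus)
                key = (ov, prod.product_id)
                if best is None or (key[0], ) > (best[0], ) or (
                    key[0] == best[0] and key[1] < best[1]
                ):
                    best = (ov, prod.product_id, hit, off5, off3, nta)
        if best is None:
            continue
        _, pid, hit, off5, off3, nta = best
        k = (pid, aln.tag.sequence)
        row = rows.setdefault(
            k,
            {
                "product_id": pid,
                "sequence": aln.tag.sequence,
                "offset5": off5,
                "offset3": off3,
                "nta": nta,
                "count_f3": 0,
                "count_f4": 0,
            },
        )
        row["count_f3"] += aln.tag.count_f3
        row["count_f4"] += aln.tag.count_f4
    cols = ["product_id", "sequence", "offset5", "offset3", "nta", "count_f3", "count_f4"]
    return pd.DataFrame(list(rows.values()), columns=cols)


def catalog_isomirs(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-product isomiR summary with reference selection and arm dominance.

    The reference isomiR is the variant with the highest summed read count
    (ties: lexicographically smallest sequence).  For gene ids shared by a
    mature and a star product, ``arm_dominance`` is "star" when the star
    product's total reads exceed the mature's, else "mature".

    Returns one row per product: product_id, reference_sequence,
    reference_length, n_isomirs, total_f3, total_f4, arm_dominance.
    """
    if assignments.empty:
        return pd.DataFrame(
            columns=[
                "product_id", "reference_sequence", "reference_length",
                "n_isomirs", "total_f3", "total_f4", "arm_dominance",
            ]
        )
    df = assignments.copy()
    df["total"] = df["count_f3"] + df["count_f4"]
    out = []
    for pid, grp in df.groupby("product_id"):
        best = grp.sort_values(
            ["total", "sequence"], ascending=[False, True]
        ).iloc[0]
        out.append(
            {
                "product_id": pid,
                "reference_sequence": best["sequence"],
                "reference_length": len(best["sequence"]),
                "n_isomirs": grp["sequence"].nunique(),
                "total_f3": int(grp["count_f3"].sum()),
                "total_f4": int(grp["count_f4"].sum()),
            }
        )
    summary = pd.DataFrame(out).set_index("product_id")
    totals = summary["total_f3"] + summary["total_f4"]
    dominance = {}
    for pid in summary.index:
        gene, _, kind = pid.rpartition("|")
        partner = f"{gene}|{'star' if kind == 'mature' else 'mature'}"
        if kind == "mature":
            star_total = totals.get(partner, 0)
            dominance[pid] = "star" if star_total > totals[pid] else "mature"
        else:
            mature_total = totals.get(partner, 0)
            dominance[pid] = "star" if totals[pid] > mature_total else "mature"
    summary["arm_dominance"] = pd.Series(dominance)
    return summary.reset_index()
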