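import pandas as pd
import pytest

from srnaforge.align import Hit, TagAlignment
from srnaforge.annotate import (
    AnnotationSet,
    KnownProduct,
    assign_known,
    catalog_isomirs,
    classify_tag,
    classify_tags,
)
from srnaforge.loci import GenomicLocus
from srnaforge.preprocess import UniqueTag


def aln(seq, loci, counts=(1, 0), mismatches=()):
    tag = UniqueTag(seq, *counts)
    hits = [Hit(seq, GenomicLocus.parse(l), tuple(mismatches)) for l in loci]
    return TagAlignment(tag, hits)


@pytest.fixture
def annotation():
    ann = AnnotationSet()
    ann.add(GenomicLocus("c", 100, 600, "+"), "rRNA", "rrn1")
    ann.add(GenomicLocus("c", 550, 650, "+"), "exon", "gene1.e1")
    ann.add(GenomicLocus("c", 1000, 1080, "+"), "tRNA", "trn1")
    ann.add(GenomicLocus("c", 2000, 2021, "+"), "miRNA", "mir1-mature")
    return ann


class TestClassifyTag:
    def test_priority_trna_over_mrna(self):
        ann = AnnotationSet()
        ann.add(GenomicLocus("c", 100, 180, "+"), "tRNA", "t")
        ann.add(GenomicLocus("c", 150, 400, "+"), "exon", "e")
        a = aln("A" * 22, ["c:150-171+"])
        assert classify_tag(a, ann) == "tRNA"

    def test_no_hits_is_unmapped(self, annotation):
        assert classify_tag(aln("A" * 22, []), annotation) == "unmapped"

    def test_repeat_flag_wins(self, annotation):
        a = aln("A" * 22, [])
        a.repeat = True
        assert classify_tag(a, annotation) == "repeat"

    def test_known_mirna_needs_16nt_same_strand_overlap(self, annotation):
        assert classify_tag(aln("A" * 22, ["c:2000-2021+"]), annotation) == "known_mirna"
        # 10-nt overlap is not enough; falls through to candidate
        assert classify_tag(aln("A" * 22, ["c:2012-2033+"]), annotation) == "candidate"
        # opposite strand does not count
        assert classify_tag(aln("A" * 22, ["c:2000-2021-"]), annotation) == "candidate"

    def test_partition_is_total(self, annotation):
        alignments = [
            aln("A" * 22, ["c:150-171+"]),
            aln("C" * 22, []),
            aln("G" * 22, ["c:5000-5021+"]),
        ]
        df = classify_tags(alignments, annotation)
        assert len(df) == 3 and df["category"].notna().all()


class TestAssignKnown:
    PRODUCTS = [
        KnownProduct("mir1|mature", GenomicLocus("c", 2000, 2021, "+")),
        KnownProduct("mir1|star", GenomicLocus("c", 2040, 2061, "+")),
    ]

    def test_exact_match_zero_offsets(self):
        df = assign_known([aln("A" * 22, ["c:2000-2021+"], (3, 4))], self.PRODUCTS)
        row = df.iloc[0]
        assert row["product_id"] == "mir1|mature"
        assert (row["offset5"], row["offset3"]) == (0, 0)
        assert (row["count_f3"], row["count_f4"]) == (3, 4)

    def test_five_prime_shift_recorded(self):
        df = assign_known([aln("A" * 22, ["c:2001-2022+"])], self.PRODUCTS)
        assert df.iloc[0]["offset5"] == 1

    def test_star_region_assigns_to_star_product(self):
        df = assign_known([aln("A" * 22, ["c:2040-2061+"])], self.PRODUCTS)
        assert df.iloc[0]["product_id"] == "mir1|star"

    def test_nta_tail_detected_and_excluded_from_offset(self):
        # 23-nt tag: 22 templated + one non-templated 3' A (mismatch at L-1)
        df = assign_known(
            [aln("G" * 22 + "A", ["c:2000-2022+"], mismatches=[22])],
            self.PRODUCTS,
        )
        row = df.iloc[0]
        assert row["nta"] == "A" and row["offset3"] == 0

    def test_out_of_bounds_offset_unassigned(self):
        df = assign_known([aln("A" * 22, ["c:2008-2029+"])], self.PRODUCTS)
        assert df.empty

    def test_minus_strand_offsets_in_transcript_sense(self):
        prods = [KnownProduct("m|mature", GenomicLocus("c", 500, 521, "-"))]
        # tag 5' end sits at genomic end for minus-strand products
        df = assign_known([aln("A" * 22, ["c:499-520-"])], prods)
        assert (df.iloc[0]["offset5"], df.iloc[0]["offset3"]) == (1, 1)


class TestCatalogIsomirs:
    def test_reference_is_most_abundant_variant(self):
        # the printed example: a 23-nt variant with 4453 reads outweighs the
        # 22-nt database sequence with 3477 reads
        table = pd.DataFrame(
            [
                {"product_id": "mir205|mature", "sequence": "U" * 23,
                 "offset5": 0, "offset3": 1, "nta": "",
                 "count_f3": 4453, "count_f4": 0},
                {"product_id": "mir205|mature", "sequence": "U" * 22,
                 "offset5": 0, "offset3": 0, "nta": "",
                 "count_f3": 3477, "count_f4": 0},
            ]
        )
        summary = catalog_isomirs(table)
        assert summary.iloc[0]["reference_length"] == 23
        assert summary.iloc[0]["n_isomirs"] == 2

    def test_star_dominance_flag(self):
        # printed counts: miR-30e 3,652 reads vs miR-30e* 16,200 reads
        table = pd.DataFrame(
            [
                {"product_id": "mir30e|mature", "sequence": "A" * 22,
                 "offset5": 0, "offset3": 0, "nta": "",
                 "count_f3": 0, "count_f4": 3652},
                {"product_id": "mir30e|star", "sequence": "C" * 22,
                 "offset5": 0, "offset3": 0, "nta": "",
                 "count_f3": 0, "count_f4": 16200},
            ]
        )
        summary = catalog_isomirs(table).set_index("product_id")
        assert summary.loc["mir30e|mature", "arm_dominance"] == "star"
        assert summary.loc["mir30e|star", "arm_dominance"] == "star"

    def test_single_variant_product(self):
        table = pd.DataFrame(
            [{"product_id": "m|mature", "sequence": "ACG" * 7, "offset5": 0,
              "offset3": 0, "nta": "", "count_f3": 5, "count_f4": 0}]
        )
        summary = catalog_isomirs(table)
        assert summary.iloc[0]["n_isomirs"] == 1
        assert summary.iloc[0]["reference_sequence"] == "ACG" * 7

    def test_tie_broken_lexicographically(self):
        table = pd.DataFrame(
            [
                {"product_id": "m|mature", "sequence": "CCC" * 7, "offset5": 0,
                 "offset3": 0, "nta": "", "count_f3": 5, "count_f4": 0},
                {"product_id": "m|mature", "sequence": "AAA" * 7, "offset5": 0,
                 "offset3": 0, "nta": "", "count_f3": 5, "count_f4": 0},
            ]
        )
        assert catalog_isomirs(table).iloc[0]["reference_sequence"] == "AAA" * 7

    def test_counts_conserved(self):
        table = pd.DataFrame(
            [
                {"product_id": "m|mature", "sequence": "A" * 20, "offset5": 0,
                 "offset3": 0, "nta": "", "count_f3": 7, "count_f4": 1},
                {"product_id": "m|mature", "sequence": "A" * 21, "offset5": 0,
                 "offset3": 1, "nta": "", "count_f3": 2, "count_f4": 3},
            ]
        )
        s = catalog_isomirs(table).iloc[0]
        assert (s["total_f3"], s["total_f4"]) == (9, 4)
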