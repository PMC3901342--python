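import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnaforge import energies
from srnaforge.hairpin import (
    MIN_HAIRPIN,
    FoldResult,
    HairpinRules,
    PrecursorWindow,
    evaluate_hairpin,
    extract_precursor_windows,
    fold_mfe,
    infer_star,
)
from srnaforge.loci import GenomicLocus, revcomp

# ---------------------------------------------------------------------------
# exhaustive enumeration oracle over all legal single-stem structures


def _pairable(a, b):
    return energies.PAIR_TABLE[a, b] >= 0


def enumerate_mfe(seq: str) -> float:
    """Minimum energy over every single stem-loop structure, by brute force.

    Walks every chain of nested pairs (outermost first), scoring stacks,
    bulges/internal loops and the closing hairpin with the same parameter
    table as the folder but none of its dynamic-programming machinery.
    """
    s = seq.upper().replace("T", "U")
    codes = energies.encode(s)
    n = len(codes)
    best = [0.0]

    def chain(i, j, acc):
        # close with a hairpin loop
        if j - i - 1 >= MIN_HAIRPIN:
            total = acc + energies.hairpin_dg(j - i - 1)
            if total < best[0]:
                best[0] = total
        # or continue with an interior pair
        for k in range(i + 1, j - MIN_HAIRPIN - 1):
            for l in range(k + MIN_HAIRPIN + 1, j):
                if not _pairable(codes[k], codes[l]):
                    continue
                a, b = k - i - 1, j - l - 1
                if a == 0 and b == 0:
                    cost = energies.STACK[
                        energies.pair_code(codes[i], codes[j]),
                        energies.pair_code(codes[k], codes[l]),
                    ]
                elif a == 0 or b == 0:
                    cost = energies.bulge_dg(a + b)
                else:
                    cost = energies.internal_dg(a + b)
                chain(k, l, acc + cost)

    for i in range(n):
        for j in range(i + MIN_HAIRPIN + 1, n):
            if _pairable(codes[i], codes[j]):
                term = (
                    energies.TERMINAL_AU
                    if energies.is_au_like(energies.pair_code(codes[i], codes[j]))
                    else 0.0
                )
                chain(i, j, term)
    return best[0]


class TestFoldMfe:
    def test_unfoldable_sequence_is_flat(self):
        res = fold_mfe("A" * 15)
        assert res.structure == "." * 15 and res.delta_g == 0.0

    def test_three_gc_stacks_plus_tetraloop(self):
        res = fold_mfe("GGGGAAAACCCC")
        gc = energies.PAIR_CODE["GC"]
        expected = 3 * energies.STACK[gc, gc] + energies.hairpin_dg(4)
        assert res.structure == "((((....))))"
        assert res.delta_g == pytest.approx(expected)

    def test_long_gc_stem_clears_discovery_gate(self):
        arm = "GGCAGCGGCCAGCGGCAGCGCGGCC"  # 25 nt, GC-rich
        res = fold_mfe(arm + "AAAAAAAA" + revcomp(arm))
        assert res.delta_g <= -20.0

    def test_non_nucleotide_characters_rejected(self):
        with pytest.raises(ValueError):
            fold_mfe("ACGNACGUACGUACG")

    def test_structure_is_balanced_single_stem(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGU"), size=60))
            res = fold_mfe(seq)
            assert len(res.structure) == len(seq)
            assert res.structure.count("(") == res.structure.count(")")
            closed = res.structure.find(")")
            if closed >= 0:
                assert "(" not in res.structure[closed:]

    @pytest.mark.parametrize(
        "seq",
        [
            "GGGAAACCCAUGCAUG",
            "GCGCGCAAAAGCGCGC",
            "AUGGCUAGCUAAGCUAGCCA",
            "GGUGCAUAAAAUGCACC",
        ],
    )
    def test_equals_enumeration_on_fixed_sequences(self, seq):
        assert fold_mfe(seq).delta_g == pytest.approx(enumerate_mfe(seq))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_equals_enumeration_on_random_short_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGU"), size=int(rng.integers(8, 15))))
        assert fold_mfe(seq).delta_g == pytest.approx(enumerate_mfe(seq))

    def test_reverse_complement_of_perfect_stem_has_equal_energy(self):
        arm = "GGCAGCGGCCAGCGGCAGCG"
        stem = arm + "AAAAAAAA" + revcomp(arm)
        assert fold_mfe(stem).delta_g == pytest.approx(
            fold_mfe(revcomp(stem)).delta_g
        )


class TestExtractWindows:
    GENOME = {"chrom1": "ACGT" * 1000}

    def test_default_window_arithmetic(self):
        hit = GenomicLocus("chrom1", 1001, 1022, "+")
        wins = {w.arm: w for w in extract_precursor_windows(hit, self.GENOME)}
        assert (wins["5p"].locus.start, wins["5p"].locus.end) == (996, 1085)
        assert (wins["3p"].locus.start, wins["3p"].locus.end) == (938, 1027)
        assert all(w.locus.length == 90 for w in wins.values())
        assert wins["5p"].mature_span == (5, 26)

    def test_window_near_chromosome_start_dropped(self):
        hit = GenomicLocus("chrom1", 3, 24, "+")
        wins = {w.arm: w for w in extract_precursor_windows(hit, self.GENOME)}
        assert "3p" not in wins  # clipped below mature + 15
        assert "5p" in wins

    def test_minus_strand_window_is_reverse_complemented(self):
        hit = GenomicLocus("chrom1", 1001, 1022, "-")
        wins = {w.arm: w for w in extract_precursor_windows(hit, self.GENOME)}
        w = wins["5p"]
        genomic = self.GENOME["chrom1"][w.locus.start - 1 : w.locus.end]
        assert w.sequence == revcomp(genomic).upper().replace("T", "U")
        m0, m1 = w.mature_span
        assert w.sequence[m0 : m1 + 1] == revcomp(
            self.GENOME["chrom1"][1000:1022]
        ).upper().replace("T", "U")


class TestEvaluateHairpin:
    def _window(self, seq, mature_span):
        return PrecursorWindow(
            arm="5p",
            locus=GenomicLocus("c", 1, len(seq), "+"),
            sequence=seq.replace("T", "U"),
            mature_span=mature_span,
        )

    def _good_stem(self):
        arm = "GGCAGCGGCCAGCGGCAGCGCGGCC"
        return arm + "AAAAAAAA" + revcomp(arm), (0, 21)

    def test_marginal_energy_fails_with_reason(self):
        seq, mspan = self._good_stem()
        window = self._window(seq, mspan)
        fold = dataclasses.replace(fold_mfe(window.sequence), delta_g=-19.5)
        cand = evaluate_hairpin(window, fold, HairpinRules(precursor_min=40))
        assert not cand.pass_rules and "delta_g" in cand.reasons

    def test_mature_spanning_loop_fails(self):
        seq, _ = self._good_stem()
        window = self._window(seq, (20, 41))  # crosses the terminal loop
        cand = evaluate_hairpin(
            window, fold_mfe(window.sequence), HairpinRules(precursor_min=40)
        )
        assert not cand.pass_rules and "mature_in_loop" in cand.reasons

    def test_sound_stem_passes_and_gate_holds(self):
        seq, mspan = self._good_stem()
        window = self._window(seq, mspan)
        cand = evaluate_hairpin(
            window, fold_mfe(window.sequence), HairpinRules(precursor_min=40)
        )
        assert cand.pass_rules and cand.fold.delta_g <= -20.0
        assert cand.mature_arm == "5p"

    def test_mature_outside_window_raises(self):
        seq, _ = self._good_stem()
        with pytest.raises(ValueError):
            evaluate_hairpin(self._window(seq, (0, len(seq))), fold_mfe(seq))


class TestInferStar:
    def test_perfect_duplex_dicer_geometry(self):
        # 22-bp duplex with unpaired flanks; mature on the 5p arm
        structure = "." * 4 + "(" * 22 + "." * 8 + ")" * 22 + "." * 4
        fold = FoldResult("N" * len(structure), structure, -30.0)
        star = infer_star(fold, (4, 25))
        pt = fold.pair_table()
        assert star == (pt[23], pt[4] + 2)
        assert star[1] - star[0] + 1 == 22

    def test_bulged_partner_changes_star_length(self):
        # one unpaired base inside the 3' arm: star is 23 nt
        structure = (
            "." * 4 + "(" * 22 + "." * 8 + ")" * 10 + "." + ")" * 12 + "." * 4
        )
        fold = FoldResult("N" * len(structure), structure, -30.0)
        star = infer_star(fold, (4, 25))
        assert star is not None and star[1] - star[0] + 1 == 23

    def test_short_partner_gives_none(self):
        structure = "." * 4 + "(" * 10 + "." * 8 + ")" * 10 + "." * 8
        fold = FoldResult("N" * len(structure), structure, -10.0)
        assert infer_star(fold, (4, 13)) is None
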