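"""Stem-loop folding, precursor excision, hairpin quality rules, star inference.

The folder is a minimum-free-energy dynamic program restricted to single
stem-loop structures: one helix (with bulges and internal loops) closed by
one terminal hairpin loop, no multibranch junctions.  That restriction is
all pre-miRNA validation needs, and it keeps an exhaustive enumeration
oracle feasible for small sequences.  Energies come from the
nearest-neighbor ΔG°37 table in :mod:`srnaforge.energies`: Watson-Crick and
GU wobble stacking terms, loop initiation penalties by size, and a terminal
AU/GU penalty on the outermost pair.  Unpaired exterior bases contribute
nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .energies import (
    PAIR_TABLE,
    STACK,
    TERMINAL_AU,
    bulge_dg,
    encode,
    hairpin_dg,
    internal_dg,
    is_au_like,
)
from .loci import GenomicLocus, revcomp

#: largest number of unpaired bases allowed in one bulge/internal loop
MAX_LOOP = 30
#: smallest sterically possible hairpin loop
MIN_HAIRPIN = 3

__all__ = [
    "FoldResult",
    "HairpinRules",
    "HairpinCandidate",
    "PrecursorWindow",
    "fold_mfe",
    "extract_precursor_windows",
    "evaluate_hairpin",
    "infer_star",
]


@dataclass(frozen=True)
class FoldResult:
    """A sequence with its single-stem MFE structure and free energy."""

    sequence: str
    structure: str
    delta_g: float  # kcal/mol at 37 C

    def pair_table(self) -> list[int]:
        """partner index per position, -1 if unpaired."""
        pt = [-1] * len(self.structure)
        stack: list[int] = []
        for i, c in enumerate(self.structure):
            if c == "(":
                stack.append(i)
            elif c == ")":
                j = stack.pop()
                pt[i], pt[j] = j, i
        return pt


def _interior_loop_costs() -> np.ndarray:
    """cost[a, b] of an interior loop with a/b unpaired bases on each side."""
    cost = np.full((MAX_LOOP + 1, MAX_LOOP + 1), np.inf)
    for a in range(MAX_LOOP + 1):
        for b in range(MAX_LOOP + 1):
            n = a + b
            if n == 0 or n > MAX_LOOP:
                continue  # 0/0 is a stack, handled with the pair-specific table
            cost[a, b] = bulge_dg(n) if (a == 0 or b == 0) else internal_dg(n)
    return cost


_LOOP_COST = _interior_loop_costs()


def fold_mfe(sequence: str) -> FoldResult:
    """Fold into the minimum-free-energy single stem-loop.

    Returns an all-dot structure with ΔG = 0 when no structure of negative
    energy exists.  Accepts ACGT or ACGU, any case.
    """
    seq = sequence.upper().replace("T", "U")
    codes = encode(seq)
    n = len(codes)
    pc = PAIR_TABLE[codes[:, None], codes[None, :]]  # pair code or -1

    INF = np.inf
    E = np.full((n, n), INF)
    # traceback: interior pair (K, L); K == -1 means close with hairpin loop
    K = np.full((n, n), -2, dtype=np.int32)
    L = np.full((n, n), -2, dtype=np.int32)

    for span in range(MIN_HAIRPIN + 1, n):  # span = j - i
        for i in range(n - span):
            j = i + span
            if pc[i, j] < 0:
                continue
            best = hairpin_dg(span - 1)
            bk, bl = -1, -1
            # stacked pair
            if pc[i + 1, j - 1] >= 0 and E[i + 1, j - 1] < INF:
                cand = E[i + 1, j - 1] + STACK[pc[i, j], pc[i + 1, j - 1]]
                if cand < best:
                    best, bk, bl = cand, i + 1, j - 1
            # bulge / internal loop to interior pair (k, l)
            k_hi = min(i + 1 + MAX_LOOP, j - MIN_HAIRPIN - 2)
            l_lo = max(i + 2 + MIN_HAIRPIN, j - 1 - MAX_LOOP)
            if k_hi >= i + 1 and j - 1 >= l_lo:
                sub = E[i + 1 : k_hi + 1, l_lo : j].copy()
                a_sizes = np.arange(0, k_hi - i)  # k - i - 1
                b_sizes = j - 1 - np.arange(l_lo, j)  # j - l - 1
                sub += _LOOP_COST[np.ix_(a_sizes, b_sizes)]
                if sub.size:
                    flat = np.argmin(sub)
                    val = sub.flat[flat]
                    if val < best:
                        ai, bi = divmod(flat, sub.shape[1])
                        best, bk, bl = val, i + 1 + ai, l_lo + bi
            if best < INF:
                E[i, j] = best
                K[i, j], L[i, j] = bk, bl

    # choose the best outermost pair, terminal AU/GU penalty applied there
    best_dg = 0.0
    best_ij: tuple[int, int] | None = None
    for i in range(n):
        for j in range(i + MIN_HAIRPIN + 1, n):
            if E[i, j] < INF:
                dg = E[i, j] + (TERMINAL_AU if is_au_like(pc[i, j]) else 0.0)
                if dg < best_dg - 1e-12:
                    best_dg, best_ij = dg, (i, j)

    structure = ["."] * n
    if best_ij is not None:
        i, j = best_ij
        while True:
            structure[i], structure[j] = "(", ")"
            if K[i, j] == -1:
                break
            i, j = int(K[i, j]), int(L[i, j])
    else:
        best_dg = 0.0
    return FoldResult(seq, "".join(structure), float(best_dg))


# ---------------------------------------------------------------------------
# precursor excision


@dataclass(frozen=True)
class PrecursorWindow:
    """A candidate precursor window around a mapped mature read."""

    arm: str  # hypothesised mature arm: "5p" or "3p"
    locus: GenomicLocus
    sequence: str  # window sequence, transcript orientation
    mature_span: tuple[int, int]  # 0-based inclusive offsets within sequence


def extract_precursor_windows(
    hit_locus: GenomicLocus,
    genome: dict[str, str],
    window_length: int = 90,
    flank: int = 5,
) -> list[PrecursorWindow]:
    """Excise up to two precursor hypotheses around a mapped tag.

    Hypothesis ``5p`` anchors the window at the mature 5' end minus *flank*
    and extends *window_length* downstream (transcript orientation);
    hypothesis ``3p`` anchors at the mature 3' end plus *flank* and extends
    upstream.  Windows are clipped at chromosome edges and a hypothesis is
    dropped when clipping leaves less than mature length + 15 nt.
    """
    chrom_seq = genome[hit_locus.chrom]
    chrom_len = len(chrom_seq)
    mature_len = hit_locus.length
    out: list[PrecursorWindow] = []
    if hit_locus.strand == "+":
        spans = {
            "5p": (hit_locus.start - flank, hit_locus.start - flank + window_length - 1),
            "3p": (hit_locus.end + flank - window_length + 1, hit_locus.end + flank),
        }
    else:
        spans = {
            "5p": (hit_locus.end + flank - window_length + 1, hit_locus.end + flank),
            "3p": (hit_locus.start - flank, hit_locus.start - flank + window_length - 1),
        }
    for arm, (ws, we) in spans.items():
        ws, we = max(1, ws), min(chrom_len, we)
        if we - ws + 1 < mature_len + 15:
            continue
        seq = chrom_seq[ws - 1 : we]
        if hit_locus.strand == "-":
            seq = revcomp(seq)
            m0 = we - hit_locus.end
        else:
            m0 = hit_locus.start - ws
        m1 = m0 + mature_len - 1
        if m0 < 0 or m1 >= len(seq):
            continue
        out.append(
            PrecursorWindow(
                arm=arm,
                locus=GenomicLocus(hit_locus.chrom, ws, we, hit_locus.strand),
                sequence=seq.upper().replace("T", "U"),
                mature_span=(m0, m1),
            )
        )
    return out


# ---------------------------------------------------------------------------
# hairpin quality rules


@dataclass(frozen=True)
class HairpinRules:
    """Rule-based pre-miRNA plausibility gate.

    A transparent surrogate for black-box hairpin classifiers: every
    threshold is explicit and configurable, and each failure carries a
    reason code.
    """

    dg_max: float = -20.0  # kcal/mol; candidate fails above this
    min_frac_mature_paired: float = 0.60
    loop_min: int = 3
    loop_max: int = 25
    precursor_min: int = 50
    precursor_max: int = 150
    star_min_len: int = 16
    trim_max_gap: int = 8  # largest interior loop the precursor helix may span


@dataclass
class HairpinCandidate:
    window: PrecursorWindow
    fold: FoldResult
    mature_arm: str | None  # 5p/3p as determined from the fold, not the hypothesis
    mature_span: tuple[int, int]
    star_span: tuple[int, int] | None
    n_paired_mature: int
    loop_span: tuple[int, int] | None
    precursor_locus: GenomicLocus | None
    pass_rules: bool
    reasons: list[str] = field(default_factory=list)


def _single_stem_spans(structure: str):
    """(outermost pair, loop span) for a single stem-loop, else None."""
    first = structure.find("(")
    last = structure.rfind(")")
    if first < 0 or last < 0:
        return None
    inner = structure[first : last + 1]
    # single terminal loop: no '(' after the first ')'
    close = inner.find(")")
    if "(" in inner[close:]:
        return None
    k0 = first + inner.rfind("(", 0, close)
    l0 = first + close
    return (first, last), (k0 + 1, l0 - 1)


def evaluate_hairpin(
    window: PrecursorWindow,
    fold: FoldResult,
    rules: HairpinRules = HairpinRules(),
) -> HairpinCandidate:
    """Apply the rule gate to a folded window.

    Pass requires: ΔG ≤ ``dg_max``; exactly one terminal loop; the mature
    span confined to one arm; ≥ ``min_frac_mature_paired`` of mature bases
    paired; loop size within bounds; and the trimmed precursor (outermost
    pair ± 2 nt) within the length window.
    """
    m0, m1 = window.mature_span
    if m0 < 0 or m1 >= len(fold.sequence) or m0 > m1:
        raise ValueError("mature span outside window")
    reasons: list[str] = []
    if fold.delta_g > rules.dg_max:
        reasons.append("delta_g")

    spans = _single_stem_spans(fold.structure)
    arm = None
    loop_span = None
    prec_locus = None
    n_paired = 0
    star = None
    if spans is None:
        reasons.append("no_stem" if "(" not in fold.structure else "multibranch")
    else:
        (i0, j0), loop_span = spans
        ls, le = loop_span
        loop_size = le - ls + 1
        if not (rules.loop_min <= loop_size <= rules.loop_max):
            reasons.append("loop_size")
        if m1 < ls:
            arm = "5p"
        elif m0 > le:
            arm = "3p"
        else:
            reasons.append("mature_in_loop")
        pt = fold.pair_table()
        n_paired = sum(1 for k in range(m0, m1 + 1) if pt[k] >= 0)
        if n_paired < rules.min_frac_mature_paired * (m1 - m0 + 1):
            reasons.append("mature_pairing")
        # trim the reported precursor by walking the helix outward from the
        # terminal loop and stopping at the first interior loop larger than
        # trim_max_gap: pairs beyond a big gap are spurious flank structure,
        # not part of the precursor helix
        chain = [(k, pt[k]) for k in range(len(pt)) if pt[k] > k]
        idx = len(chain) - 1
        while idx > 0:
            (ci, cj), (ni, nj) = chain[idx - 1], chain[idx]
            gap = (ni - ci - 1) + (cj - nj - 1)
            if gap > rules.trim_max_gap:
                break
            idx -= 1
        a0, b0 = chain[idx]
        t0, t1 = max(0, a0 - 2), min(len(fold.sequence) - 1, b0 + 2)
        prec_len = t1 - t0 + 1
        if not (rules.precursor_min <= prec_len <= rules.precursor_max):
            reasons.append("precursor_length")
        prec_locus = _offsets_to_locus(window.locus, t0, t1)
        if arm is not None:
            star = infer_star(fold, window.mature_span, min_len=rules.star_min_len)
    return HairpinCandidate(
        window=window,
        fold=fold,
        mature_arm=arm,
        mature_span=window.mature_span,
        star_span=star,
        n_paired_mature=n_paired,
        loop_span=loop_span,
        precursor_locus=prec_locus,
        pass_rules=not reasons,
        reasons=reasons,
    )


def _offsets_to_locus(window_locus: GenomicLocus, o0: int, o1: int) -> GenomicLocus:
    """Map 0-based offsets in transcript orientation back to genome coords."""
    if window_locus.strand == "+":
        return GenomicLocus(
            window_locus.chrom, window_locus.start + o0, window_locus.start + o1, "+"
        )
    return GenomicLocus(
        window_locus.chrom, window_locus.end - o1, window_locus.end - o0, "-"
    )


def infer_star(
    fold: FoldResult, mature_span: tuple[int, int], min_len: int = 16
) -> tuple[int, int] | None:
    """Star span from Dicer duplex geometry (2-nt 3' overhangs on both ends).

    The star strand is the pairing partner of the mature span, shifted so
    that each strand of the duplex carries a 2-nt 3' overhang.  Unpaired
    mature ends are projected through the nearest paired base.  Returns
    None when the partner region is shorter than *min_len* nt.
    """
    pt = fold.pair_table()
    n = len(pt)
    m0, m1 = mature_span

    def project(k: int, step: int) -> int | None:
        """partner of position k, extrapolated if k itself is unpaired."""
        q = k
        while 0 <= q < n and pt[q] < 0:
            q += step
        if not (0 <= q < n):
            return None
        # extrapolate along the helix for the unpaired offset
        return pt[q] + (q - k)

    # star 3' end pairs opposite mature 5' end, + 2-nt overhang
    a = project(m0, +1)
    # star 5' end pairs opposite mature position m1 - 2
    b = project(m1 - 2, -1)
    if a is None or b is None:
        return None
    ends = sorted((a + 2, b))
    s0, s1 = max(0, ends[0]), min(n - 1, ends[1])
    if s1 - s0 + 1 < min_len:
        return None
    return (s0, s1)
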