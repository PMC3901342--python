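"""Synthetic genomes, planted miRNA truth, and two-library read simulation.

The generator emulates the study design the analysis assumes: two small-RNA
libraries (F3 "castrated", F4 "intact") of 15-35 nt inserts sequenced to a
fixed read length with a 3' adapter, drawn from a genome carrying planted
pre-miRNA stem-loops.  Plantings cover the structural variety the
discovery stages must handle: clustered loci (inter-locus gaps < 10 kb),
mirtrons coinciding with annotated introns, multi-copy loci, known genes
(exported as a mature+hairpin reference), conserved novels (exported with
<= 2 substitutions as an ortholog set), decoy loci that emit reads but fold
poorly (negatives for discovery precision), and rRNA/tRNA contamination.

Counts are Poisson per product and library — matching the assumption of
the replicate-free DE test — around means that encode planted log2 fold
changes; reads are realized as the reference isomiR plus 5'/3' offset
variants with geometrically decaying abundance and occasional non-templated
3' A/U additions.  Identical configurations (including the seed) produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hairpin import HairpinRules, evaluate_hairpin, fold_mfe, infer_star, PrecursorWindow
from .loci import GenomicLocus, revcomp

__all__ = [
    "SimConfig",
    "SimTruth",
    "TrueGene",
    "PlacementError",
    "GenomeBuild",
    "generate_genome",
    "plant_mirna_loci",
    "simulate_libraries",
    "simulate",
    "write_outputs",
    "length_survey_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class PlacementError(RuntimeError):
    """Raised when a planting cannot be placed after bounded retries."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic two-library experiment.

    Defaults describe the standard study conditions used throughout the
    test-suite: a 2 x 1 Mb genome, 100 planted hairpin loci, ~100k reads
    per library, moderate isomiR spread and 10% ncRNA contamination.
    """

    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_mirna_loci: int = 100
    n_clustered: int = 12  # planted as clusters of 3 with gaps < 10 kb
    n_mirtrons: int = 5
    n_multicopy: int = 4
    n_known: int = 30
    n_conserved_novel: int = 20
    n_decoys: int = 30  # read-emitting non-hairpin loci (discovery negatives)
    frac_de: float = 0.3
    fc_magnitude: float = 2.0  # |log2 fold change| of planted DE products
    mean_depth: int = 100_000  # expected reads per library
    isomir_decay: float = 0.3  # geometric decay of offset-variant abundance
    nta_prob: float = 0.05
    contam_frac: float = 0.10
    star_fraction: float = 0.15  # mean star/mature abundance ratio
    n_star_dominant: int = 2
    adapter: str = "CGCCTTGGCCGTACAGCAG"
    read_length: int = 35
    overdispersion: float = 0.0  # gamma-Poisson shape^-1; 0 = pure Poisson
    error_rate: float = 0.0  # per-base substitution rate (robustness only)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length": self.chrom_length,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        for name in (
            "n_mirna_loci", "n_clustered", "n_mirtrons", "n_multicopy",
            "n_known", "n_conserved_novel", "n_decoys", "mean_depth",
            "n_star_dominant",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("frac_de", "isomir_decay", "nta_prob", "contam_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_known + self.n_conserved_novel > self.n_mirna_loci:
            raise ValueError("n_known + n_conserved_novel exceeds n_mirna_loci")
        if self.n_clustered + self.n_mirtrons + self.n_multicopy > self.n_mirna_loci:
            raise ValueError("special plantings exceed n_mirna_loci")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class TrueGene:
    gene_id: str
    loci: list[GenomicLocus]  # >1 entry for multi-copy genes
    precursor_seq: str  # transcript orientation, DNA alphabet
    mature_locus: GenomicLocus
    star_locus: GenomicLocus | None
    mature_seq: str
    star_seq: str | None
    arm: str  # 5p | 3p
    status: str  # known | conserved_novel | specific_novel
    mirtron: bool = False
    cluster_id: str | None = None


@dataclass
class SimTruth:
    config: SimConfig
    chrom_lengths: dict[str, int]
    genes: list[TrueGene]
    decoys: list[GenomicLocus]
    contam_loci: list[tuple[str, GenomicLocus]]  # (feature type, locus)
    introns: list[GenomicLocus]
    expression: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class GenomeBuild:
    """Mutable genome plus annotation features accumulated while planting."""

    config: SimConfig
    chroms: dict[str, bytearray]
    features: list[tuple[GenomicLocus, str, str]] = field(default_factory=list)
    reserved: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def sequences(self) -> dict[str, str]:
        return {c: s.decode() for c, s in self.chroms.items()}

    def reserve(self, chrom: str, start: int, end: int) -> bool:
        """Reserve [start, end] (1-based) if free; False when occupied."""
        if start < 1 or end > len(self.chroms[chrom]):
            return False
        taken = self.reserved.setdefault(chrom, [])
        for s, e in taken:
            if start <= e and s <= end:
                return False
        taken.append((start, end))
        return True

    def write(self, chrom: str, start: int, seq: str) -> None:
        """Overwrite genome bases at 1-based start."""
        self.chroms[chrom][start - 1 : start - 1 + len(seq)] = seq.encode()


def _random_seq(rng: np.random.Generator, n: int, p=None) -> str:
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


def generate_genome(config: SimConfig) -> GenomeBuild:
    """Uniform-random chromosomes plus ncRNA and gene-model annotation.

    Plants rRNA/tRNA/snoRNA contaminant source loci and protein-coding
    gene models (exon-intron-exon); mirtron hosts are added later by
    :func:`plant_mirna_loci` when the precursor lengths are known.
    """
    rng = np.random.default_rng([config.seed, 0])
    chroms = {
        f"Chr{i + 1}": bytearray(_random_seq(rng, config.chrom_length).encode())
        for i in range(config.n_chromosomes)
    }
    return GenomeBuild(config=config, chroms=chroms)


def _place(
    build: GenomeBuild,
    rng: np.random.Generator,
    length: int,
    margin: int = 200,
    chrom: str | None = None,
    constraint: str = "locus",
    tries: int = 300,
) -> GenomicLocus:
    names = [chrom] if chrom else sorted(build.chroms)
    for _ in range(tries):
        c = names[int(rng.integers(len(names)))]
        hi = len(build.chroms[c]) - margin - length
        if hi <= margin:
            continue
        start = int(rng.integers(margin, hi))
        if build.reserve(c, start - 60, start + length - 1 + 60):
            strand = "+" if rng.random() < 0.5 else "-"
            return GenomicLocus(c, start, start + length - 1, strand)
    raise PlacementError(
        f"could not place a {length}-bp {constraint} after {tries} tries; "
        "genome too small or too crowded"
    )


def _plant_contaminants(build: GenomeBuild, rng: np.random.Generator):
    out = []
    for ftype, length, n in (("rRNA", 500, 4), ("tRNA", 80, 6), ("snoRNA", 150, 3)):
        for i in range(n):
            loc = _place(build, rng, length, constraint=ftype)
            build.write(loc.chrom, loc.start, _random_seq(rng, length))
            build.features.append((loc, ftype, f"{ftype}-{i + 1}"))
            out.append((ftype, loc))
    return out


def _make_precursor(rng: np.random.Generator) -> tuple[str, int, int]:
    """(precursor DNA seq, arm length, loop length) with a guaranteed stem.

    The 3' arm is the reverse complement of the 5' arm with two internal
    mismatches, as in natural pre-miRNAs whose stems are imperfect; a
    GC-biased arm keeps the fold well below the -20 kcal/mol gate despite
    the resulting 1x1 internal loops.
    """
    arm_len = int(rng.integers(21, 24))
    loop_len = int(rng.integers(8, 16))
    # arms with internal self-structure are redrawn: a self-folding arm
    # can pass the energy gate inside a window that contains one arm only
    for _ in range(100):
        arm = _random_seq(rng, arm_len, p=[0.22, 0.28, 0.28, 0.22])
        if fold_mfe(arm).delta_g > -5.0 and fold_mfe(revcomp(arm)).delta_g > -5.0:
            break
    loop = _random_seq(rng, loop_len)
    arm3 = list(revcomp(arm))
    for pos in (arm_len // 3, (2 * arm_len) // 3):
        cur = arm3[pos]
        arm3[pos] = str(rng.choice([b for b in "ACGT" if b != cur]))
    return arm + loop + "".join(arm3), arm_len, loop_len


def _fold_truth(precursor: str, arm_len: int, arm: str):
    """Validate the planted stem and derive mature/star spans from the fold."""
    n = len(precursor)
    mature_span = (0, arm_len - 1) if arm == "5p" else (n - arm_len, n - 1)
    window = PrecursorWindow(
        arm=arm,
        locus=GenomicLocus("sim", 1, n, "+"),
        sequence=precursor.replace("T", "U"),
        mature_span=mature_span,
    )
    fold = fold_mfe(precursor)
    rules = HairpinRules(precursor_min=min(50, n))
    cand = evaluate_hairpin(window, fold, rules)
    star_span = infer_star(fold, mature_span)
    return cand, mature_span, star_span


def plant_mirna_loci(build: GenomeBuild, config: SimConfig) -> SimTruth:
    """Write precursors into the genome and return the planted truth.

    Placement order: clusters, mirtrons (inside freshly annotated introns),
    multi-copy genes, then isolated loci.  The first ``n_known`` genes are
    known (reference FASTA), the next ``n_conserved_novel`` conserved
    novels (ortholog FASTA, mutated later), the rest specific novels.
    Every planted precursor is folded and must pass the hairpin gate;
    failures are redrawn a bounded number of times.
    """
    rng = np.random.default_rng([config.seed, 1])
    contam = _plant_contaminants(build, rng)

    genes: list[TrueGene] = []
    introns: list[GenomicLocus] = []
    # planting plan: clusters of 3 (a remainder of 1 folds into the last
    # cluster so no planted cluster is a singleton), then mirtrons,
    # multi-copy genes, then isolated loci
    cluster_sizes: list[int] = []
    left = config.n_clustered
    while left >= 2:
        take = 3 if left != 4 and left >= 3 else 2
        cluster_sizes.append(take)
        left -= take
    if left == 1 and cluster_sizes:
        cluster_sizes[-1] += 1
        left = 0
    plan: list[tuple[str, int]] = [("cluster", s) for s in cluster_sizes]
    plan += [("mirtron", 1)] * config.n_mirtrons
    plan += [("multicopy", 1)] * config.n_multicopy
    n_planned = sum(s for _, s in plan)
    plan += [("plain", 1)] * (config.n_mirna_loci - n_planned)

    def new_validated_precursor():
        for _ in range(50):
            precursor, arm_len, _loop = _make_precursor(rng)
            arm = "5p" if rng.random() < 0.5 else "3p"
            cand, mspan, sspan = _fold_truth(precursor, arm_len, arm)
            if cand.pass_rules and sspan is not None:
                return precursor, arm, mspan, sspan
        raise PlacementError("could not draw a precursor passing the hairpin gate")

    def spans_to_loci(locus: GenomicLocus, span):
        o0, o1 = span
        if locus.strand == "+":
            return GenomicLocus(locus.chrom, locus.start + o0, locus.start + o1, "+")
        return GenomicLocus(locus.chrom, locus.end - o1, locus.end - o0, "-")

    def write_precursor(locus: GenomicLocus, precursor: str) -> None:
        build.write(
            locus.chrom,
            locus.start,
            precursor if locus.strand == "+" else revcomp(precursor),
        )
        # unpairable flanks (A/A in transcript sense) stop the stem from
        # extending into random flanking sequence, so the discovered
        # precursor ends stay close to the planted boundaries; 10 nt is
        # wider than the largest interior loop the precursor trimmer will
        # walk across, making extension through the pad impossible
        pad = ("A" if locus.strand == "+" else "T") * 10
        if locus.start - 10 >= 1:
            build.write(locus.chrom, locus.start - 10, pad)
        if locus.end + 10 <= len(build.chroms[locus.chrom]):
            build.write(locus.chrom, locus.end + 1, pad)

    def add_gene(gid, locus, precursor, arm, mspan, sspan, mirtron=False,
                 cluster_id=None, extra_loci=()):
        write_precursor(locus, precursor)
        mature_locus = spans_to_loci(locus, mspan)
        star_locus = spans_to_loci(locus, sspan) if sspan else None
        m0, m1 = mspan
        mature_seq = precursor[m0 : m1 + 1]
        star_seq = None
        if sspan:
            s0, s1 = sspan
            star_seq = precursor[s0 : s1 + 1]
        genes.append(
            TrueGene(
                gene_id=gid,
                loci=[locus, *extra_loci],
                precursor_seq=precursor,
                mature_locus=mature_locus,
                star_locus=star_locus,
                mature_seq=mature_seq,
                star_seq=star_seq,
                arm=arm,
                status="specific_novel",  # classes assigned below
                mirtron=mirtron,
                cluster_id=cluster_id,
            )
        )

    i = 0
    cluster_n = 0
    for kind, size in plan:
        if kind == "cluster":
            cluster_n += 1
            cid = f"true-cluster-{cluster_n}"
            prev_end = None
            chrom = None
            for _member in range(size):
                precursor, arm, mspan, sspan = new_validated_precursor()
                if prev_end is None:
                    # a wide end margin leaves room for the whole chain
                    loc = _place(build, rng, len(precursor), margin=25_000,
                                 constraint="cluster seed")
                    chrom = loc.chrom
                else:
                    loc = None
                    for _try in range(50):
                        gap = int(rng.integers(500, 8000))
                        start = prev_end + gap
                        cand_loc = GenomicLocus(
                            chrom, start, start + len(precursor) - 1,
                            "+" if rng.random() < 0.5 else "-",
                        )
                        if build.reserve(chrom, cand_loc.start - 60,
                                         cand_loc.end + 60):
                            loc = cand_loc
                            break
                    if loc is None:
                        raise PlacementError(
                            "could not extend a planted cluster within 10 kb"
                        )
                gid = f"sim-mir-{i + 1}"
                add_gene(gid, loc, precursor, arm, mspan, sspan, cluster_id=cid)
                prev_end = loc.end
                i += 1
            continue
        gid = f"sim-mir-{i + 1}"
        precursor, arm, mspan, sspan = new_validated_precursor()
        if kind == "mirtron":
            # gene model: exon - intron(= precursor) - exon, same strand
            exon = 150
            total = exon + len(precursor) + exon
            gene_loc = _place(build, rng, total, constraint="mirtron host gene")
            g0 = gene_loc.start
            intron = GenomicLocus(
                gene_loc.chrom, g0 + exon, g0 + exon + len(precursor) - 1,
                gene_loc.strand,
            )
            build.features.append((gene_loc, "gene", f"host-{gid}"))
            build.features.append(
                (GenomicLocus(gene_loc.chrom, g0, g0 + exon - 1, gene_loc.strand),
                 "exon", f"host-{gid}.e1")
            )
            build.features.append((intron, "intron", f"host-{gid}.i1"))
            build.features.append(
                (GenomicLocus(gene_loc.chrom, intron.end + 1, gene_loc.end,
                              gene_loc.strand), "exon", f"host-{gid}.e2")
            )
            introns.append(intron)
            add_gene(gid, intron, precursor, arm, mspan, sspan, mirtron=True)
        elif kind == "multicopy":
            loc = _place(build, rng, len(precursor), constraint="multicopy primary")
            copy = _place(build, rng, len(precursor), chrom=loc.chrom,
                          constraint="multicopy duplicate")
            copy = GenomicLocus(copy.chrom, copy.start, copy.end, loc.strand)
            write_precursor(copy, precursor)
            add_gene(gid, loc, precursor, arm, mspan, sspan, extra_loci=(copy,))
        else:
            loc = _place(build, rng, len(precursor), constraint="miRNA locus")
            add_gene(gid, loc, precursor, arm, mspan, sspan)
        i += 1

    # status assignment: shuffle so special kinds are spread across classes
    order = rng.permutation(len(genes))
    for rank, idx in enumerate(order):
        if rank < config.n_known:
            genes[idx].status = "known"
        elif rank < config.n_known + config.n_conserved_novel:
            genes[idx].status = "conserved_novel"

    # annotation features for known genes
    for g in genes:
        if g.status != "known":
            continue
        for loc in g.loci:
            build.features.append((loc, "pre_miRNA", g.gene_id))
        build.features.append((g.mature_locus, "miRNA", f"{g.gene_id}-mature"))
        if g.star_locus is not None:
            build.features.append((g.star_locus, "miRNA_star", f"{g.gene_id}-star"))

    decoys = []
    ac = np.frombuffer(b"AC", dtype="S1")
    for d in range(config.n_decoys):
        loc = _place(build, rng, 22, constraint="decoy locus")
        # A/C-only insert and padding cannot base-pair (no Watson-Crick or
        # GU partner within the alphabet), so decoy windows never fold:
        # guaranteed negatives for discovery specificity.  Plus strand
        # only — a minus-strand transcript would be G/U-only, which can
        # wobble-pair with itself.
        loc = GenomicLocus(loc.chrom, loc.start, loc.end, "+")
        pad = 20
        start = max(1, loc.start - pad)
        ln = min(len(build.chroms[loc.chrom]), loc.end + pad) - start + 1
        build.write(
            loc.chrom, start, rng.choice(ac, size=ln).tobytes().decode()
        )
        decoys.append(loc)

    return SimTruth(
        config=config,
        chrom_lengths={c: len(s) for c, s in build.chroms.items()},
        genes=genes,
        decoys=decoys,
        contam_loci=contam,
        introns=introns,
    )


# ---------------------------------------------------------------------------
# read simulation


def _poisson(rng: np.random.Generator, mean: float, overdispersion: float) -> int:
    if mean <= 0:
        return 0
    if overdispersion > 0:
        shape = 1.0 / overdispersion
        mean = rng.gamma(shape, mean / shape)
    return int(rng.poisson(mean))


def _isomir_variants(
    genome: dict[str, str], locus: GenomicLocus, decay: float
) -> tuple[list[str], list[float], list[int]]:
    """Offset variants of the product at *locus* with geometric weights."""
    seqs, weights, off3s = [], [], []
    chrom_seq = genome[locus.chrom]
    offsets = [(0, 0)] if decay == 0 else [
        (o5, o3) for o5 in (-1, 0, 1) for o3 in (-2, -1, 0, 1, 2)
    ]
    for o5, o3 in offsets:
        if locus.strand == "+":
            s, e = locus.start + o5, locus.end + o3
        else:
            s, e = locus.start - o3, locus.end - o5
        if s < 1 or e > len(chrom_seq) or e - s + 1 < 15:
            continue
        seq = chrom_seq[s - 1 : e]
        if locus.strand == "-":
            seq = revcomp(seq)
        d = abs(o5) + abs(o3)
        seqs.append(seq.upper())
        weights.append(decay ** d if d else 1.0)
        off3s.append(o3)
    return seqs, weights, off3s


def _next_genomic_base(genome: dict[str, str], locus: GenomicLocus, o3: int) -> str:
    """Templated base just 3' of the variant end (transcript sense)."""
    chrom_seq = genome[locus.chrom]
    if locus.strand == "+":
        pos = locus.end + o3 + 1
        if pos > len(chrom_seq):
            return "N"
        return chrom_seq[pos - 1].upper()
    pos = locus.start - o3 - 1
    if pos < 1:
        return "N"
    return revcomp(chrom_seq[pos - 1]).upper()


def simulate_libraries(
    truth: SimTruth, build: GenomeBuild
) -> tuple[list[str], list[str]]:
    """Realize the two read libraries; fills ``truth.expression`` in place.

    Returns the raw read sequences (insert + adapter, cut to the read
    length) for libraries F3 and F4.  Per product, the F3 count is
    Poisson(base * 2^(+lfc/2)) and the F4 count Poisson(base * 2^(-lfc/2)),
    so the planted log2 fold change is log2(F3/F4) expectation.
    """
    config = truth.config
    rng = np.random.default_rng([config.seed, 2])
    genome = build.sequences()

    products = []  # (product_id, locus, weight multiplier)
    for g in truth.genes:
        w = float(rng.lognormal(0.0, 1.2))
        star_dom = False
        products.append([f"{g.gene_id}|mature", g.mature_locus, w])
        if g.star_locus is not None:
            ratio = float(rng.uniform(0.05, config.star_fraction * 2))
            products.append([f"{g.gene_id}|star", g.star_locus, w * ratio])
    # promote a few stars to dominance; only known genes carry the planted
    # dominance, since novel-gene arms are named by abundance downstream
    known_ids = {g.gene_id for g in truth.genes if g.status == "known"}
    star_rows = [
        p for p in products
        if p[0].endswith("|star") and p[0].rpartition("|")[0] in known_ids
    ]
    for p in star_rows[: config.n_star_dominant]:
        p[2] *= 30.0
    for k, loc in enumerate(truth.decoys):
        products.append([f"decoy-{k + 1}", loc, float(rng.lognormal(-1.0, 0.8))])

    total_w = sum(p[2] for p in products)
    mirna_depth = config.mean_depth * (1.0 - config.contam_frac)

    rows = []
    reads: dict[str, list[str]] = {"F3": [], "F4": []}
    for pid, locus, w in products:
        base = w / total_w * mirna_depth
        lfc = 0.0
        if config.frac_de > 0 and rng.random() < config.frac_de:
            lfc = config.fc_magnitude * (1 if rng.random() < 0.5 else -1)
        mean_f3 = base * 2 ** (lfc / 2)
        mean_f4 = base * 2 ** (-lfc / 2)
        k3 = _poisson(rng, mean_f3, config.overdispersion)
        k4 = _poisson(rng, mean_f4, config.overdispersion)
        seqs, weights, off3s = _isomir_variants(genome, locus, config.isomir_decay)
        probs = np.array(weights) / sum(weights)
        for lib, k in (("F3", k3), ("F4", k4)):
            if k == 0:
                continue
            split = rng.multinomial(k, probs)
            for seq, o3, n_var in zip(seqs, off3s, split):
                if n_var == 0:
                    continue
                n_nta = int(rng.binomial(n_var, config.nta_prob))
                for _ in range(n_var - n_nta):
                    reads[lib].append(seq)
                for _ in range(n_nta):
                    templ = _next_genomic_base(genome, locus, o3)
                    base_nt = "A" if rng.random() < 0.5 else "T"
                    if base_nt == templ:
                        base_nt = "T" if base_nt == "A" else "A"
                    reads[lib].append(seq + base_nt)
        rows.append(
            {
                "product_id": pid,
                "locus": str(locus),
                "mean_f3": mean_f3,
                "mean_f4": mean_f4,
                "log2fc": lfc,
                "is_de": lfc != 0.0,
                "realized_f3": k3,
                "realized_f4": k4,
            }
        )

    # contaminant reads from the planted ncRNA loci
    contam_depth = config.mean_depth * config.contam_frac
    if truth.contam_loci:
        per_locus = contam_depth / len(truth.contam_loci)
        for ftype, loc in truth.contam_loci:
            for lib in ("F3", "F4"):
                k = _poisson(rng, per_locus, config.overdispersion)
                for _ in range(k):
                    ln = int(rng.integers(18, 31))
                    off = int(rng.integers(0, loc.length - ln + 1))
                    sub = genome[loc.chrom][loc.start - 1 + off : loc.start - 1 + off + ln]
                    if loc.strand == "-":
                        sub = revcomp(sub)
                    reads[lib].append(sub.upper())

    truth.expression = pd.DataFrame(rows)

    def finish(seq: str) -> str:
        read = (seq + config.adapter)[: config.read_length]
        if len(read) < config.read_length:
            read = read + "A" * (config.read_length - len(read))
        if config.error_rate > 0:
            chars = list(read)
            for j in range(len(chars)):
                if rng.random() < config.error_rate:
                    chars[j] = "ACGT"[int(rng.integers(4))]
            read = "".join(chars)
        return read

    return [finish(s) for s in reads["F3"]], [finish(s) for s in reads["F4"]]


def simulate(config: SimConfig):
    """Full generation pass: genome, truth, and both read libraries."""
    build = generate_genome(config)
    truth = plant_mirna_loci(build, config)
    reads_f3, reads_f4 = simulate_libraries(truth, build)
    return build, truth, reads_f3, reads_f4


def length_survey_reads(
    rng: np.random.Generator,
    n: int = 2000,
    adapter: str = "CGCCTTGGCCGTACAGCAG",
    min_insert: int = 10,
    max_insert: int = 45,
    read_length: int = 60,
) -> list[str]:
    """Reads whose insert lengths span a range wider than the retention
    window, for exercising the preprocessing length gate."""
    out = []
    for _ in range(n):
        ln = int(rng.integers(min_insert, max_insert + 1))
        insert = _random_seq(rng, ln)
        read = (insert + adapter)[:read_length]
        if len(read) < read_length:
            read += "A" * (read_length - len(read))
        out.append(read)
    return out


# ---------------------------------------------------------------------------
# file outputs


def write_outputs(
    build: GenomeBuild,
    truth: SimTruth,
    reads_f3: list[str],
    reads_f4: list[str],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the standard file set; returns the path of each artifact."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([truth.config.seed, 3])
    paths: dict[str, Path] = {}

    p = paths["genome"] = out / "genome.fa"
    with open(p, "w") as fh:
        for chrom, seq in build.sequences().items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    p = paths["annotation"] = out / "annotation.gff3"
    with open(p, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, ln in truth.chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {ln}\n")
        for k, (loc, ftype, name) in enumerate(build.features):
            fh.write(
                f"{loc.chrom}\tsrnaforge_sim\t{ftype}\t{loc.start}\t{loc.end}"
                f"\t.\t{loc.strand}\t.\tID={ftype}-{k + 1};Name={name}\n"
            )

    for lib, reads in (("F3", reads_f3), ("F4", reads_f4)):
        p = paths[f"reads_{lib.lower()}"] = out / f"reads_{lib}.fastq"
        with open(p, "w") as fh:
            for i, seq in enumerate(reads):
                fh.write(f"@{lib}_read{i + 1}\n{seq}\n+\n{'I' * len(seq)}\n")

    known = [g for g in truth.genes if g.status == "known"]
    p = paths["known_mature"] = out / "known_mature.fa"
    with open(p, "w") as fh:
        for g in known:
            fh.write(f">{g.gene_id}-mature\n{g.mature_seq}\n")
    p = paths["known_hairpin"] = out / "known_hairpin.fa"
    with open(p, "w") as fh:
        for g in known:
            fh.write(f">{g.gene_id}\n{g.precursor_seq}\n")

    p = paths["ortholog_mature"] = out / "ortholog_mature.fa"
    with open(p, "w") as fh:
        for g in truth.genes:
            if g.status != "conserved_novel":
                continue
            seq = list(g.mature_seq)
            for pos in rng.choice(
                len(seq), size=int(rng.integers(0, 3)), replace=False
            ):
                cur = seq[pos]
                seq[pos] = rng.choice([b for b in "ACGT" if b != cur])
            fh.write(f">orth-{g.gene_id}\n{''.join(seq)}\n")

    p = paths["truth_loci"] = out / "truth_loci.tsv"
    rows = []
    for g in truth.genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "status": g.status,
                "loci": ";".join(str(l) for l in g.loci),
                "mature_locus": str(g.mature_locus),
                "star_locus": str(g.star_locus) if g.star_locus else "",
                "mature_seq": g.mature_seq,
                "star_seq": g.star_seq or "",
                "arm": g.arm,
                "mirtron": g.mirtron,
                "cluster_id": g.cluster_id or "",
            }
        )
    for k, loc in enumerate(truth.decoys):
        rows.append(
            {"gene_id": f"decoy-{k + 1}", "status": "decoy", "loci": str(loc),
             "mature_locus": str(loc), "star_locus": "", "mature_seq": "",
             "star_seq": "", "arm": "", "mirtron": False, "cluster_id": ""}
        )
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)

    p = paths["truth_expression"] = out / "truth_expression.tsv"
    truth.expression.to_csv(p, sep="\t", index=False)
    return paths
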