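"""End-to-end orchestration: preprocess -> align -> annotate -> hairpin ->
discover -> quantify, with TSV outputs and a summary report.

Every stage parameter defaults to the analysis' canonical value (15-35 nt
retention window, two end mismatches, -20 kcal/mol folding gate, 10 kb
cluster window, <= 2 conservation substitutions, 2-fold / p < 0.001 DE
thresholds).  Outputs are deterministic for a fixed config, and every
output table header embeds the config hash so reruns can be verified.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import align as align_mod
from . import annotate as annotate_mod
from . import discover as discover_mod
from . import hairpin as hairpin_mod
from . import io as io_mod
from . import preprocess as pre_mod
from . import quantify as quant_mod
from .loci import GenomicLocus

log = logging.getLogger("srnaforge")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "merge_library_gene_sets",
    "write_summary",
]


@dataclass
class PipelineConfig:
    genome_fasta: str = "genome.fa"
    annotation_gff3: str = "annotation.gff3"
    reads_f3: str = "reads_F3.fastq"
    reads_f4: str = "reads_F4.fastq"
    known_mature_fasta: str | None = None
    known_hairpin_fasta: str | None = None
    ortholog_mature_fasta: str | None = None
    adapter: str = "CGCCTTGGCCGTACAGCAG"
    min_len: int = 15
    max_len: int = 35
    min_overlap: int = 6
    max_mismatch_rate: float = 0.1
    min_mean_phred: float = 20.0
    max_end_mismatches: int = 2
    max_loci: int = 20
    window_length: int = 90
    flank: int = 5
    dg_max: float = -20.0
    cluster_window: int = 10_000
    conservation_max_subs: int = 2
    mirtron_tolerance: int = 3
    fc_threshold: float = 2.0
    p_threshold: float = 0.001
    pseudocount: float = 0.5
    name_prefix: str = "ssc-miR"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    tags: list
    length_distribution: pd.DataFrame
    categories: pd.DataFrame
    candidates: list  # all evaluated HairpinCandidates
    genes: list  # MirnaGene
    assignments: pd.DataFrame  # isomiR rows
    isomir_summary: pd.DataFrame
    counts: pd.DataFrame
    lib_sizes: pd.Series
    de: pd.DataFrame
    clusters: dict[str, str]
    cluster_loci: dict[str, list]
    density: pd.DataFrame
    summary: pd.DataFrame
    gene_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def gene_sets(self) -> tuple[set, set]:
        f3 = {g.gene_id for g in self.genes if g.present_f3}
        f4 = {g.gene_id for g in self.genes if g.present_f4}
        return f3, f4


def _stage(name):
    t0 = time.time()
    log.info("stage %s", name)
    return t0


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage on the configured inputs; optionally write outputs."""
    for path_attr in ("genome_fasta", "annotation_gff3", "reads_f3", "reads_f4"):
        p = getattr(config, path_attr)
        if not Path(p).exists():
            raise FileNotFoundError(f"{path_attr}: no such file {p}")

    genome = io_mod.read_genome(config.genome_fasta)
    features = io_mod.read_gff3_features(config.annotation_gff3)
    annotation = annotate_mod.AnnotationSet.from_features(features)
    introns = [loc for loc, ftype, _ in features if ftype == "intron"]
    gene_models = [loc for loc, ftype, _ in features if ftype == "gene"]
    known_pre: dict[str, list[GenomicLocus]] = {}
    known_mature: dict[str, GenomicLocus] = {}
    known_star: dict[str, GenomicLocus] = {}
    for loc, ftype, name in features:
        if ftype == "pre_miRNA":
            known_pre.setdefault(name, []).append(loc)
        elif ftype == "miRNA" and name.endswith("-mature"):
            known_mature[name[: -len("-mature")]] = loc
        elif ftype == "miRNA_star" and name.endswith("-star"):
            known_star[name[: -len("-star")]] = loc

    orthologs = (
        list(io_mod.read_fasta_dict(config.ortholog_mature_fasta).values())
        if config.ortholog_mature_fasta
        else []
    )

    # --- preprocess -------------------------------------------------------
    _stage("preprocess")

    def inserts(path):
        for read in pre_mod.read_sequences(path, config.min_mean_phred):
            tr = pre_mod.trim_adapter(
                read, config.adapter, config.min_overlap, config.max_mismatch_rate
            )
            if tr is not None:
                yield tr.insert

    tags, collapse_stats = pre_mod.collapse_libraries(
        inserts(config.reads_f3), inserts(config.reads_f4),
        config.min_len, config.max_len,
    )
    length_dist = pre_mod.summarize_length_distribution(
        tags, config.min_len, config.max_len
    )

    # --- align ------------------------------------------------------------
    _stage("align")
    index = align_mod.GenomeIndex(genome)
    alignments = [
        align_mod.align_tag(t, index, config.max_end_mismatches, config.max_loci)
        for t in tags
    ]

    # --- classify ---------------------------------------------------------
    _stage("classify")
    categories = annotate_mod.classify_tags(alignments, annotation)
    cat_by_tag = dict(zip(categories["tag"], categories["category"]))

    # --- hairpin folding on locus groups ---------------------------------
    _stage("hairpin")
    mirna_alignments = [
        a for a in alignments
        if cat_by_tag[a.tag.sequence] in ("known_mirna", "candidate")
    ]
    rules = hairpin_mod.HairpinRules(dg_max=config.dg_max)
    candidates = _fold_locus_groups(mirna_alignments, genome, config, rules)

    # --- discover ---------------------------------------------------------
    _stage("discover")
    genes, _locus_to_gene = discover_mod.call_novel(
        [c for c in candidates if c.pass_rules], known_pre
    )
    # known genes whose hairpin window failed the fold still exist as genes
    # when reads overlap their annotated mature locus
    have = {g.gene_id for g in genes}
    for gid, mloc in known_mature.items():
        if gid in have or gid not in known_pre:
            continue
        covered = any(
            h.locus.strand == mloc.strand and mloc.overlap(h.locus) >= 16
            for a in mirna_alignments
            for h in a.hits
        )
        if not covered:
            continue
        mseq = genome[mloc.chrom][mloc.start - 1 : mloc.end]
        if mloc.strand == "-":
            from .loci import revcomp as _rc
            mseq = _rc(mseq)
        genes.append(
            discover_mod.MirnaGene(
                gene_id=gid, name=gid, loci=list(known_pre[gid]),
                mature_sequence=mseq, star_sequence=None, status="known",
            )
        )

    # product loci per gene
    products: list[annotate_mod.KnownProduct] = []
    for g in genes:
        if g.status == "known" and g.gene_id in known_mature:
            products.append(
                annotate_mod.KnownProduct(f"{g.gene_id}|mature", known_mature[g.gene_id])
            )
            if g.gene_id in known_star:
                products.append(
                    annotate_mod.KnownProduct(f"{g.gene_id}|star", known_star[g.gene_id])
                )
            continue
        if not g.candidates:
            continue
        best = min(g.candidates, key=lambda c: c.fold.delta_g)
        m0, m1 = best.mature_span
        arm_a = hairpin_mod._offsets_to_locus(best.window.locus, m0, m1)
        arm_b = None
        if best.star_span is not None:
            s0, s1 = best.star_span
            arm_b = hairpin_mod._offsets_to_locus(best.window.locus, s0, s1)
        # for novel genes the mature arm is the more abundant one: the
        # folding window was seeded from a read that may sit on either arm
        if arm_b is not None and g.status != "known":
            cov_a = _arm_coverage(arm_a, mirna_alignments)
            cov_b = _arm_coverage(arm_b, mirna_alignments)
            if cov_b > cov_a:
                arm_a, arm_b = arm_b, arm_a
                g.mature_sequence, g.star_sequence = (
                    g.star_sequence or g.mature_sequence,
                    g.mature_sequence,
                )
        products.append(annotate_mod.KnownProduct(f"{g.gene_id}|mature", arm_a))
        if arm_b is not None:
            products.append(annotate_mod.KnownProduct(f"{g.gene_id}|star", arm_b))

    # --- isomiR assignment and counting ----------------------------------
    _stage("quantify")
    assignments = annotate_mod.assign_known(mirna_alignments, products)
    isomir_summary = annotate_mod.catalog_isomirs(assignments)
    if assignments.empty:
        raise RuntimeError("no reads assigned to any miRNA product")
    counts, lib_sizes = quant_mod.build_counts(assignments)

    # the gene's mature sequence is its reference isomiR (most abundant
    # variant), which is what conservation classification should see
    ref_by_pid = dict(
        zip(isomir_summary["product_id"], isomir_summary["reference_sequence"])
    )
    for g in genes:
        ref = ref_by_pid.get(f"{g.gene_id}|mature")
        if ref:
            g.mature_sequence = ref

    gene_totals_f3: dict[str, int] = {}
    gene_totals_f4: dict[str, int] = {}
    for pid, row in counts.iterrows():
        gid = pid.rpartition("|")[0]
        gene_totals_f3[gid] = gene_totals_f3.get(gid, 0) + int(row["raw_f3"])
        gene_totals_f4[gid] = gene_totals_f4.get(gid, 0) + int(row["raw_f4"])
    for g in genes:
        g.present_f3 = gene_totals_f3.get(g.gene_id, 0) >= 1
        g.present_f4 = gene_totals_f4.get(g.gene_id, 0) >= 1
    genes = [g for g in genes if g.present_f3 or g.present_f4]

    # conservation classes and per-library naming, genomic order
    counters: dict[tuple[str, str], int] = {}
    for g in sorted(genes, key=lambda g: (g.primary_locus.chrom, g.primary_locus.start)):
        if g.status == "known":
            continue
        g.status = discover_mod.classify_conservation(
            g.mature_sequence, orthologs, config.conservation_max_subs
        )
        lib = "F3" if g.present_f3 else "F4"
        cls = "C" if g.status == "conserved_novel" else "S"
        n = counters.get((lib, cls), 0) + 1
        counters[(lib, cls)] = n
        g.name = f"{config.name_prefix}-{lib}-{cls}{n}"

    # clusters, mirtrons, intergenic, density
    all_loci = [(g.gene_id, loc) for g in genes for loc in g.loci]
    clusters, cluster_loci = discover_mod.detect_clusters(
        all_loci, config.cluster_window
    )
    mirtrons = discover_mod.detect_mirtrons(all_loci, introns, config.mirtron_tolerance)
    for g in genes:
        g.cluster_id = clusters.get(g.gene_id)
        g.mirtron = mirtrons.get(g.gene_id, False)
        g.intergenic = not any(
            any(gm.overlap(loc) > 0 for gm in gene_models) for loc in g.loci
        )
    density = discover_mod.genomic_density(
        [loc for _, loc in all_loci], {c: len(s) for c, s in genome.items()}
    )

    # --- differential expression -----------------------------------------
    de = quant_mod.call_de(
        counts, lib_sizes,
        fc_threshold=config.fc_threshold,
        p_threshold=config.p_threshold,
        pseudocount=config.pseudocount,
    )

    gene_table = _gene_table(genes)
    summary = write_summary(genes, de, isomir_summary, clusters, density, config)

    result = PipelineResult(
        config=config,
        tags=tags,
        length_distribution=length_dist,
        categories=categories,
        candidates=candidates,
        genes=genes,
        assignments=assignments,
        isomir_summary=isomir_summary,
        counts=counts,
        lib_sizes=lib_sizes,
        de=de,
        clusters=clusters,
        cluster_loci=cluster_loci,
        density=density,
        summary=summary,
        gene_table=gene_table,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _arm_coverage(arm: GenomicLocus, alignments) -> int:
    """Total reads of tags whose hits substantially overlap an arm locus."""
    total = 0
    for a in alignments:
        if any(
            h.locus.strand == arm.strand and arm.overlap(h.locus) >= 16
            for h in a.hits
        ):
            total += a.tag.total
    return total


def _fold_locus_groups(alignments, genome, config, rules):
    """Fold one representative window set per overlapping-hit locus group.

    Each distinct expressed locus is folded once (for the most abundant tag
    covering it) rather than once per isomiR, which leaves the candidate
    set unchanged while keeping the folding budget proportional to the
    number of loci.
    """
    hits = []
    for a in alignments:
        for h in a.hits:
            hits.append((h.locus.chrom, h.locus.strand, h.locus.start, h, a.tag))
    hits.sort(key=lambda x: (x[0], x[1], x[2]))
    groups: list[list] = []
    for chrom, strand, start, h, tag in hits:
        if (
            groups
            and groups[-1][-1][0] == chrom
            and groups[-1][-1][1] == strand
            and start <= groups[-1][-1][3].locus.end
        ):
            groups[-1].append((chrom, strand, start, h, tag))
        else:
            groups.append([(chrom, strand, start, h, tag)])
    candidates = []
    for grp in groups:
        _, _, _, h, tag = max(grp, key=lambda x: (x[4].total, x[3].locus.start))
        evaluated = [
            hairpin_mod.evaluate_hairpin(
                window, hairpin_mod.fold_mfe(window.sequence), rules
            )
            for window in hairpin_mod.extract_precursor_windows(
                h.locus, genome, config.window_length, config.flank
            )
        ]
        # keep the best passing arm hypothesis only; failures are all kept
        # so their reason codes appear in the candidate report
        passing = [c for c in evaluated if c.pass_rules]
        if passing:
            best = min(passing, key=lambda c: c.fold.delta_g)
            candidates.append(best)
        candidates.extend(c for c in evaluated if not c.pass_rules)
    return candidates


def _gene_table(genes) -> pd.DataFrame:
    rows = [
        {
            "gene_id": g.gene_id,
            "name": g.name,
            "status": g.status,
            "loci": ";".join(str(l) for l in g.loci),
            "n_loci": len(g.loci),
            "mature_sequence": g.mature_sequence,
            "star_sequence": g.star_sequence or "",
            "mirtron": g.mirtron,
            "cluster_id": g.cluster_id or "",
            "intergenic": g.intergenic,
            "present_f3": g.present_f3,
            "present_f4": g.present_f4,
        }
        for g in genes
    ]
    return pd.DataFrame(rows)


def merge_library_gene_sets(genes_f3: set, genes_f4: set) -> dict:
    """Union/common bookkeeping for the two per-library gene sets."""
    common = genes_f3 & genes_f4
    union = genes_f3 | genes_f4
    return {
        "n_f3": len(genes_f3),
        "n_f4": len(genes_f4),
        "n_common": len(common),
        "n_union": len(union),
        "union": union,
        "common": common,
    }


def write_summary(genes, de, isomir_summary, clusters, density, config) -> pd.DataFrame:
    """Headline tallies: per-library class counts, DE totals, percentages."""
    rows = []
    sets = merge_library_gene_sets(
        {g.gene_id for g in genes if g.present_f3},
        {g.gene_id for g in genes if g.present_f4},
    )
    for lib, flag in (("F3", "present_f3"), ("F4", "present_f4")):
        present = [g for g in genes if getattr(g, flag)]
        known = sum(1 for g in present if g.status == "known")
        cons = sum(1 for g in present if g.status == "conserved_novel")
        spec = sum(1 for g in present if g.status == "specific_novel")
        rows.append(
            {"metric": f"genes_{lib}", "value": len(present),
             "detail": f"known={known};conserved_novel={cons};specific_novel={spec}"}
        )
    rows.append({"metric": "genes_common", "value": sets["n_common"], "detail": ""})
    rows.append({"metric": "genes_union", "value": sets["n_union"], "detail": ""})
    n_up = int((de["call"] == "up").sum())
    n_down = int((de["call"] == "down").sum())
    n_de_genes = len({
        pid.rpartition("|")[0] for pid in de.index[de["call"] != "ns"]
    })
    pct = round(100.0 * n_de_genes / sets["n_union"], 1) if sets["n_union"] else 0.0
    rows.append({"metric": "de_up", "value": n_up, "detail": ""})
    rows.append({"metric": "de_down", "value": n_down, "detail": ""})
    rows.append({"metric": "de_total_products", "value": n_up + n_down, "detail": ""})
    rows.append({"metric": "de_genes_pct_of_union", "value": pct, "detail": ""})
    if not isomir_summary.empty:
        rows.append(
            {"metric": "isomirs_per_product", "value": "",
             "detail": f"min={int(isomir_summary['n_isomirs'].min())};"
                       f"max={int(isomir_summary['n_isomirs'].max())}"}
        )
    rows.append(
        {"metric": "n_clusters", "value": len(set(clusters.values())), "detail": ""}
    )
    rows.append(
        {"metric": "n_mirtrons", "value": sum(1 for g in genes if g.mirtron),
         "detail": ""}
    )
    n_novel = sum(1 for g in genes if g.status != "known")
    n_intergenic = sum(1 for g in genes if g.status != "known" and g.intergenic)
    pct_ig = round(100.0 * n_intergenic / n_novel, 1) if n_novel else 0.0
    rows.append({"metric": "novel_intergenic_pct", "value": pct_ig,
                 "detail": f"{n_intergenic}/{n_novel}"})
    for _, r in density.iterrows():
        rows.append(
            {"metric": f"density_{r['chrom']}", "value": r["density_per_mb"],
             "detail": f"n={int(r['n_loci'])}"}
        )
    return pd.DataFrame(rows, columns=["metric", "value", "detail"])


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    h = result.config.config_hash
    result.config.to_yaml(outdir / "config.yaml")
    io_mod.write_tags_fasta(result.tags, outdir / "tags.fa")
    tag_df = pd.DataFrame(
        [{"sequence": t.sequence, "count_f3": t.count_f3, "count_f4": t.count_f4}
         for t in result.tags]
    )
    io_mod.write_tsv(tag_df, outdir / "tags.tsv", h)
    io_mod.write_tsv(
        result.length_distribution.reset_index(), outdir / "length_distribution.tsv", h
    )
    io_mod.write_tsv(result.categories, outdir / "categories.tsv", h)
    cand_df = pd.DataFrame(
        [
            {
                "locus": str(c.precursor_locus) if c.precursor_locus else "",
                "delta_g": round(c.fold.delta_g, 2),
                "structure": c.fold.structure,
                "mature_span": f"{c.mature_span[0]}-{c.mature_span[1]}",
                "star_span": f"{c.star_span[0]}-{c.star_span[1]}" if c.star_span else "",
                "pass": c.pass_rules,
                "reasons": ";".join(c.reasons),
            }
            for c in result.candidates
        ]
    )
    io_mod.write_tsv(cand_df, outdir / "candidates.tsv", h)
    io_mod.write_tsv(result.gene_table, outdir / "genes.tsv", h)
    io_mod.write_tsv(result.assignments, outdir / "isomirs.tsv", h)
    io_mod.write_tsv(result.isomir_summary, outdir / "isomir_summary.tsv", h)
    io_mod.write_tsv(result.de.reset_index(), outdir / "de_results.tsv", h)
    scatter = result.de.reset_index()[
        ["product_id", "log2_norm_f3", "log2_norm_f4", "call"]
    ]
    io_mod.write_tsv(scatter, outdir / "scatter.tsv", h)
    io_mod.write_tsv(result.density, outdir / "density.tsv", h)
    cluster_df = pd.DataFrame(
        [{"gene_id": gid, "cluster_id": cid} for gid, cid in result.clusters.items()]
    )
    io_mod.write_tsv(cluster_df, outdir / "clusters.tsv", h)
    io_mod.write_tsv(result.summary, outdir / "summary.tsv", h)
    io_mod.write_bed6(
        [(g.name, loc) for g in result.genes for loc in g.loci],
        outdir / "precursors.bed",
    )
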