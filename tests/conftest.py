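"""Shared fixtures: one small and one full-scale synthetic experiment.

Both are generated once per session; the full-scale run drives the
threshold-enforcement and recovery tests, the small one everything that
only needs a working dataset.
"""

from __future__ import annotations

import pytest

from srnaforge.pipeline import PipelineConfig, run_pipeline
from srnaforge.simdata import SimConfig, simulate, write_outputs

SMALL_CONFIG = SimConfig(
    n_chromosomes=2,
    chrom_length=300_000,
    n_mirna_loci=30,
    n_clustered=6,
    n_mirtrons=3,
    n_multicopy=2,
    n_known=8,
    n_conserved_novel=6,
    n_decoys=10,
    mean_depth=20_000,
    seed=11,
)

DEFAULT_CONFIG = SimConfig(seed=1)  # 2 x 1 Mb, 100 loci, ~200k reads total


def _run(config: SimConfig, tmpdir):
    build, truth, reads_f3, reads_f4 = simulate(config)
    paths = write_outputs(build, truth, reads_f3, reads_f4, tmpdir)
    pcfg = PipelineConfig(
        genome_fasta=str(paths["genome"]),
        annotation_gff3=str(paths["annotation"]),
        reads_f3=str(paths["reads_f3"]),
        reads_f4=str(paths["reads_f4"]),
        known_mature_fasta=str(paths["known_mature"]),
        known_hairpin_fasta=str(paths["known_hairpin"]),
        ortholog_mature_fasta=str(paths["ortholog_mature"]),
        seed=config.seed,
    )
    result = run_pipeline(pcfg, tmpdir / "out")
    return build, truth, paths, result


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    build, truth, reads_f3, reads_f4 = simulate(SMALL_CONFIG)
    return build, truth, reads_f3, reads_f4


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    return _run(SMALL_CONFIG, tmp_path_factory.mktemp("small"))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    return _run(DEFAULT_CONFIG, tmp_path_factory.mktemp("default"))


def match_truth(called_genes, truth, min_ro=0.5):
    """Map called novel genes onto planted loci by reciprocal overlap."""
    matched: dict[str, list] = {}
    unmatched = []
    for g in called_genes:
        best_ro, best_tg = 0.0, None
        for tg in truth.genes:
            for tl in tg.loci:
                for loc in g.loci:
                    ro = loc.reciprocal_overlap(tl)
                    if ro > best_ro:
                        best_ro, best_tg = ro, tg
        if best_ro >= min_ro:
            matched.setdefault(best_tg.gene_id, []).append(g)
        else:
            unmatched.append(g)
    return matched, unmatched
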