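# Methods

This note documents the models, parameter choices and numerical decisions
behind `srnaforge`, and what the synthetic benchmark does and does not
demonstrate.

## Folding model

Pre-miRNA validation only requires deciding whether a window folds into a
plausible stem-loop, so the folder minimises free energy over **single
stem-loop structures**: one helix with bulges and internal loops, closed
by one terminal hairpin loop, no multibranch junctions. The restriction
buys two things: an O(n²·L) dynamic program (L = 30, the largest interior
loop considered, as in standard folders), and a feasible exhaustive
enumeration oracle — the test-suite verifies the DP against brute-force
enumeration of every legal structure for short sequences.

Energies are nearest-neighbor ΔG°37 terms shipped as a JSON table:

- Watson–Crick stacking follows the standard Turner 37 °C set
  (GC/GC −3.42 … AU/AU −0.93 kcal/mol).
- GU wobble stacks use the commonly quoted approximate values. Planted
  stems in the benchmark clear the −20 kcal/mol gate by ≥ 10 kcal/mol, so
  no tested quantity is sensitive to the exact GU parameters.
- Hairpin (sizes 3–9), bulge (1–6) and internal-loop (2–10) initiation
  penalties are tabulated, with Jacobson–Stockmayer extrapolation
  `ΔG(n) = ΔG(n_max) + 1.75·RT·ln(n/n_max)` beyond the table.
- A +0.45 kcal/mol terminal penalty applies when the outermost pair is
  AU/UA/GU/UG. Unpaired exterior bases contribute nothing.

Simplifications relative to full Turner folding: no coaxial stacking, no
sequence-dependent 1×1/2×2 interior-loop tables, no loop-asymmetry term,
no dangling ends. These shift absolute ΔG by a few kcal/mol on typical
precursors — immaterial for a −20 kcal/mol gate that real pre-miRNAs pass
by a wide margin — and keep the model exactly enumerable.

**Precursor trimming.** The reported precursor is anchored by walking the
helix outward from the terminal loop and stopping at the first interior
loop larger than `trim_max_gap` (default 8 nt), then extending 2 nt beyond
the anchor pair. Trimming to the literal outermost pair is unreliable on
excised windows: one or two chance pairs between random flanking bases,
bridging a large interior loop, can stretch the reported locus tens of
nucleotides past the biological stem, which in particular breaks mirtron
boundary matching. A helix interrupted by more than ~8 unpaired bases is
not a continuation of the precursor stem in any meaningful sense.

## Hairpin acceptance rules

Black-box hairpin classifiers are replaced by an explicit, auditable rule
set (all thresholds configurable): ΔG ≤ −20 kcal/mol; a single terminal
loop of 3–25 nt; the mature span confined to one arm; ≥ 60 % of mature
bases paired; trimmed precursor 50–150 nt. Each failure carries a reason
code in `candidates.tsv`. Candidate windows are 90 nt with a 5-nt flank,
two per mapped tag (one per arm hypothesis); of the hypotheses that pass,
only the lowest-ΔG one is kept — the discarded hypothesis is almost always
a window containing a single arm plus random flank.

The star span follows Dicer geometry: the pairing partner of the mature
span shifted to leave 2-nt 3' overhangs on both duplex ends, reading the
partner through the pair table and projecting across unpaired positions;
no star is reported when the partner region is shorter than 16 nt.

For novel genes the "mature" arm is the one with more assigned reads; the
other becomes the star. Arm dominance (a star product out-expressing its
mature) is therefore only a meaningful observation for genes whose arm
identity is fixed by external annotation, i.e. known genes.

## Alignment semantics

"Up to two end-nucleotide mismatches" is implemented as the strictest
reading: positions {0, 1, L−2, L−1} of the read may mismatch, at most two
in total (both may sit at one end), and the core must match exactly. The
implementation seeds with an exact 11-mer from the core (a 15-nt tag has
an 11-nt core) against a sorted k-mer index and verifies the full rule;
a property test asserts exact equivalence with a literal scan of every
genomic position on both strands.

## Differential expression

With no biological replicates, only technical (Poisson) variation is
testable. For product counts k₁, k₂ with effective library sizes s₁, s₂
(column sum × TMM factor), the test conditions on n = k₁+k₂:
k₁ ~ Binomial(n, p₀), p₀ = s₁/(s₁+s₂); the two-sided p sums binomial
probabilities ≤ the observed one (scipy's exact binomial test). Above
n = 100 000 a normal approximation with continuity correction is used; it
agrees with the exact tail to three significant figures well below that
point. k₁ = k₂ = 0 gives p = 1 by convention.

Calls require |log₂FC| > 1 **strictly** and p < 0.001 **strictly** — a
product at exactly 2-fold is not called, regardless of p. No
multiple-testing correction is applied, matching the raw-threshold
convention of replicate-free two-library comparisons; a Benjamini–Hochberg
option exists on the library surface. When either raw count is zero the
displayed fold change uses a 0.5 pseudocount on both normalized values;
the test itself handles zeros exactly.

TMM is implemented from its definition (M/A trimming at 30 %/5 %,
precision-weighted mean of surviving M values, factors scaled to unit
geometric mean); the suite cross-checks it against an independent direct
transcription of the formula (±5 %) and against Bioconductor edgeR's
`calcNormFactors` via Rscript.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the analysis assumes:
two libraries of fixed-length reads (35 nt, insert + 3' adapter, dummy
qualities), ~100 k reads each; planted stem-loop precursors (21–23-nt arms
with two internal mismatches, 8–15-nt loops) placed as isolated loci,
clusters with gaps of 0.5–8 kb, intron-exact mirtrons, and same-chromosome
duplicates; known/conserved/specific truth classes with exported
reference and ortholog FASTA files (orthologs mutated by ≤ 2
substitutions); per-product Poisson counts whose means encode planted
log₂ fold changes of ±2 for a 30 % subset; isomiR spectra with
geometrically decaying offset-variant abundance (decay 0.3), 5 %
non-templated 3' A/U additions; and 10 % contamination from planted
rRNA/tRNA/snoRNA loci.

Three constructions serve testability rather than realism, and are labeled
as such in the code:

- **Unpairable flanks.** Each precursor is flanked by 10-nt A-runs
  (transcript sense) so the discovered stem cannot extend into flanking
  sequence; discovered boundaries then match planted (and intron)
  boundaries to within the 2-nt trim margin.
- **Fold-negative decoys.** Decoy loci that emit reads are written in an
  A/C-only alphabet (with 20-nt padding, plus strand only) and therefore
  cannot base-pair at all: they are guaranteed negatives for discovery
  precision. Real false-positive pressure comes from genomic sequence that
  folds marginally; random 90-nt windows under the single-stem model reach
  −20 kcal/mol rarely but not never.
- **Arm self-structure rejection.** Planted arms are redrawn until they
  have no fold of their own below −5 kcal/mol, because a self-folding arm
  can pass the gate inside a window containing only that arm.

Not emulated: realistic quality profiles, ligation bias, sequencing error
(a rate knob exists, default 0), overdispersed counts (a gamma-Poisson
knob exists, default off), paralog families with near-identical matures,
and A-to-I editing. Passing the recovery tests therefore demonstrates the
pipeline's correctness under its own model assumptions, not performance on
real libraries with structured noise.

Default scale (2 chromosomes × 1 Mb, 100 loci, ~200 k reads total) runs
the full pipeline in ~20 s on one CPU; the test-suite uses a 2 × 300 kb /
30-locus configuration for everything that does not specifically exercise
full scale.

## Other numerical choices

- IsomiR offset bounds ±4 (5') / ±6 (3'), non-templated tails ≤ 3 nt of
  A/T inconsistent with the template; reference isomiR ties broken by
  lexicographically smallest sequence.
- Cluster chaining is strand-agnostic, gap measured end-to-start against a
  running maximum end (so nested loci chain correctly); the 10-kb rule is
  strict (`gap < 10000`).
- Conservation distance: Hamming on equal lengths, or ≤ 2 mismatches with
  a single end-anchored extension when lengths differ by ≤ 2.
- Novel-gene naming counters run per library and class in genomic order,
  so output names are deterministic.
- Gene-level library presence requires ≥ 1 assigned read in that library.
- Known-gene merging matches any locus of multi-copy known precursors;
  known genes whose excised window fails the fold gate are still reported
  (and quantified) from their annotation when reads cover the annotated
  mature locus.
- All stage outputs are plain TSV with a config-hash header line;
  identical config + seed reproduces byte-identical outputs.

## Known limitations

- The single-stem MFE model cannot represent multibranch folds, so a
  genuine precursor nested inside a larger structured transcript may fold
  "worse" than under a full folder; with a −20 kcal/mol gate this was
  never observed to cost a planted locus.
- Cross-mapping between paralogs with identical matures is resolved by
  locus, but reads are assigned to a single best product; fractional
  assignment is out of scope.
- The DE test inherits the Poisson assumption: with biological replicates
  or overdispersion it is anti-conservative, and the generator's
  overdispersion knob exists precisely to demonstrate that failure mode.
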