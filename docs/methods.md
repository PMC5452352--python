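# Methods

This note documents the statistical models, the data-generating process
used for validation, and the design choices where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and formats

All coordinates are 0-based half-open internally. GTF (1-based closed)
converts at the I/O boundary; BED and bedGraph pass through verbatim.
Chromosome names are taken as-is — a disjoint chromosome namespace between
gene models and regions raises a warning, never an error, because both
conventions ("1" vs "chr1") are common and silently intersecting them
would hide the problem.

## Event detection

Events are found by comparing every unordered pair of a gene's transcript
exon chains and matching five local patterns, each requiring shared anchor
exon segments on both sides:

- **IR** — one chain has an intron lying strictly inside a single exon of
  the other chain (the exon covers both intron flanks).
- **ES** — one chain has an internal exon absent from the other, and the
  other chain joins the two flanking exons at the same facing boundaries.
- **A5 / A3** — two introns share one boundary and differ at the other;
  whether the differing side is the donor (5′) or acceptor (3′) side is
  decided by strand: the donor is the boundary transcribed first.
- **MXE** — chain 1 holds internal exon A and no exonic overlap with B,
  chain 2 holds B and no overlap with A, A and B are separated by a
  non-empty gap, and both chains share the facing boundaries of the
  flanking exons.

Alternative first/last exons and complex regions match no pattern and are
deliberately not events. Exact anchor-boundary sharing is required (no
fuzz). Events de-duplicate across pairs by the key (type, chrom, strand,
alt region, flank boundaries); the event id is the first 12 hex digits of
a SHA-1 of that key, stable across runs and machines.

Two strand symmetries hold and are property-tested: relabelling the strand
at fixed coordinates swaps A5↔A3 (donor and acceptor trade places), and
mirroring all coordinates *and* flipping strand preserves every type,
because the mirrored minus-strand pair encodes the identical RNA.

Inclusion/exclusion labelling: the inclusion form is always the form with
more transcribed sequence in the alternative region (retained intron,
included exon, longer splice variant; for MXE the form carrying the
upstream-in-transcript exon). PSI is the inclusion fraction. This is
deterministic, strand-aware, and matches the common PSI convention.

## PSI and the differential-splicing test

The read model is a two-form Beta-Binomial: isoform-specific counts
(k, n−k) give Ψ | data ~ Beta(k+a, n−k+b) with a = b = 1 by default.
A read is isoform-specific when its blocks nest in exactly one form's
exons with all spanned junctions matching that form; reads compatible
with both forms (shared flank) or neither are ignored.

The test for ΔΨ ≠ 0 between conditions is a Savage–Dickey density ratio
evaluated on replicate-pooled counts: BF₁₀ = p_prior(Δ=0)/p_post(Δ=0).
Under independent Uniform(0,1) priors the prior density of Δ at 0 is
exactly 1 (triangular on [−1,1]), so only the posterior density at 0 needs
estimating: 100 000 paired Beta posterior draws, Gaussian kernel with
Silverman's-rule bandwidth floored at 0.01 (the floor caps the attainable
BF near 4×10¹ per unit density and keeps the estimate stable when the
posterior is far from 0). Each condition draws from its own RNG stream,
assigned canonically by the count pair, so swapping conditions exactly
negates the draws and the BF is exactly swap-invariant. Tests compare the
kernel estimate against exact numerical integration of the Beta-product
density.

Replicate filters (both must pass, besides BF ≥ 5):

- **Support**: ≥ 20 isoform-specific reads in ≥ 2 replicates of *each*
  condition. The source description of this rule is ambiguous between "at
  least two" and "all" replicates; both are one config value apart
  (`min_reps`), and the default follows the "at least two" reading.
- **Consistency**: the maximum pairwise within-condition spread of
  per-replicate posterior-mean PSIs must be *strictly* below the absolute
  difference of the condition means (ties fail). Replicates with zero
  informative reads are excluded from this computation but still count
  against support. Spread could equally be defined as range or variance
  and the between-condition difference on pooled PSIs; the implemented
  choice (pairwise max vs difference of means) is documented here rather
  than asserted as uniquely correct.

Mark dependence: an event significantly DiS in wild type and in neither
writer mutant is *dependent*; in wild type and every mutant, *independent*;
anything else unclassified. No multiple-testing correction is applied
across events — the Bayes-factor threshold is the only gate, matching the
analysis this package re-implements.

## Chromatin integration

Region-to-gene association defaults to full containment within the gene
span (the literal "within the start and end of the gene"); `any` and
`midpoint` overlap modes are exposed because containment is strict. The
event-distance analysis uses `any` so that boundary-straddling regions
still count. Metagene profiles use a ±2 kb window in 50-bp bins anchored
at TSS or TTS with fixed-distance (not gene-body-scaled) offsets;
minus-strand genes are reversed so positive offsets always point
downstream of transcription. Occupancy tracks are stored at 10-bp
resolution; windows snap to that grid (sub-cell shift < half a profile
bin). The distance test is a one-sided Mann–Whitney U (dependent events
closer); no particular test is canonical here, so the choice is recorded
in output metadata. scipy's "auto" method gives the exact U distribution
for small tie-free samples and the continuity-corrected normal
approximation otherwise. Track reproducibility uses Pearson correlation of
1-kb window sums after removing windows above the 0.999 quantile of either
track (guarding against a few extreme windows dominating r).

## Expression stand-in

Differential expression is *not* a negative-binomial GLM re-implementation;
it is a deliberately small, fully testable stand-in: median-of-ratios size
factors (computed over genes positive in all samples), log2(normalized+1)
transformation, and a moderated t-test with empirical-Bayes variance
shrinkage — per-gene pooled variances are shrunk toward a scaled
inverse-chi-square prior whose scale and degrees of freedom are
moment-estimated from the log-variances, and the t statistic uses the
augmented degrees of freedom. The shrinkage is what makes a 3-vs-3 design
workable at all: without cross-gene information sharing the smallest
achievable p-value at n = 3 (~10⁻⁴) cannot survive BH correction across
hundreds of genes, and sensitivity collapses to ~0 under the validation
conditions below. DEG ⇔ |log2FC| ≥ 1 and BH-adjusted p < 0.05.

Term enrichment is an upper-tail hypergeometric test with BH correction;
terms are taken as given (no ontology-graph propagation), and the
"at least five genes" reporting filter counts study-set hits (k ≥ 5),
switchable via `min_genes`.

## Phenotype

Temperature response = mean trait (DTB or RLN) at 16 °C over mean at
25 °C, formed per replicate tray and then averaged — plants are never
pooled across trays, matching the stated averaging order of the assay.
Genotypes are compared by a two-sided pooled-variance Student's t on the
per-tray ratios (the quantity plotted), not on raw per-condition values;
this choice is documented rather than asserted as the original intent.

## Synthetic data: what it emulates, and what it does not

Each generated gene carries exactly one engineered event, with the mix
defaulting to IR 0.40 / ES 0.15 / A5 0.15 / A3 0.15 / MXE 0.15 (intron
retention dominates plant splicing). Defaults define the study conditions:
baseline Ψ ~ U(0.2, 0.6); half the events truly differential with
ΔΨ = +0.3 at 25 °C; three replicates at Poisson(100) isoform-specific
reads with Binomial inclusion counts; genotypes WT/sdg8/sdg26 with
attenuation 0/1/1 applied to the ΔΨ of mark-*dependent* events (half of
the DiS events); marked-gene fractions DiS 0.96, DEG 0.65, other 0.60;
mark regions centred 500 bp downstream of the TSS (strand-aware) with
widths 300 bp (16 °C) and 450 bp (25 °C) ± 10% jitter and matching
Gaussian-bump tracks over a low gamma background; negative-binomial
expression (dispersion 0.1) with 10% DEG genes at |log2FC| = 2 drawn from
non-DiS genes so the gene classes stay disjoint; phenotypes DTB
70 → 50 days (WT) vs 70 → 69 (mutants), sd 3, rounded to the 2-day
screening grid, 3 trays × 15 plants. Genes tile one chromosome per 50
genes with 2-kb gaps and a minimum gene span of 1.5 kb (so TSS-anchored
regions stay inside the gene body under containment association).

For the dependence–distance analysis the generator has an alternative
`mark_mode="event"` placement: dependent-event genes get their region
centred on the event, independent-event genes at the TSS. The default
`"tss"` mode is used everywhere else.

Counts are generated at the event level, not by read placement; a
block-read emitter (`gen_block_reads`) exists solely to exercise the read
classifier and draws read starts uniformly along a form. Consequently the
generator does **not** emulate read-position biases, insert-size effects,
overdispersion of isoform-specific counts beyond binomial, mappability or
GC bias, NMD decay dynamics, or correlated replicate effects — passing
recovery tests demonstrate correctness of the statistical machinery under
its stated model, not robustness to those real-data phenomena.

## Validation problem sizes

The shipped checks use: 200 random genes (vs an independent segment-run
oracle) for event detection; the full (k, n) grid to n = 200 for the Beta
closed form; the default 300-event study for DiS calibration/recovery and
dependence accuracy; a 1000-gene study (≈500 genes per class) for the
marked-fraction recovery so the ±0.05 check is binomially meaningful; a
300-gene event-anchored study for the distance test; and the 60-gene demo
config for pipeline determinism. These sizes were chosen so every check is
statistically informative yet runs in seconds.

## Determinism and numerical notes

Every stochastic operation takes an explicit seed; per-event sub-seeds
derive from a SHA-1 of (base seed, genotype, event id), so results do not
depend on event order and stay below 2³¹. Pipeline re-runs with the same
config are byte-identical, with one exception: `manifest.json` carries
wall-clock timestamps. Degenerate inputs are defined, not special-cased:
(0,0) counts give the prior (Ψ = 0.5, CI 0.025–0.975); zero-read
replicates fail support; a single replicate per condition passes
consistency vacuously when means differ and fails on exact ties; empty
gene sets and empty distance samples raise.

## Known limitations

Pairwise isoform comparison cannot decompose nested/complex splicing
regions into elementary events. The Bayes factor's kernel density
estimate is biased upward near very small posterior densities (bandwidth
floor), so extreme BFs are order-of-magnitude statements — irrelevant at
the BF ≥ 5 decision boundary, where the estimate tracks exact integration
to within a few percent. The expression stand-in assumes approximate
log-normality of normalized counts and a common mean–variance trend. The
occupancy-track model has no replicate structure per condition, so the
track-correlation operation is exercised across conditions in the
pipeline rather than across true replicates.
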