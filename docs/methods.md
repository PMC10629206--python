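# Methods

This note documents the models, conventions, and numerical choices behind
each stage, what the synthetic cohorts do and do not emulate, and the
design decisions taken where more than one reading was defensible.

## Coordinates and formats

All in-memory coordinates are 0-based half-open. VCF positions are
written 1-based; BED/BEDPE/bedGraph are 0-based. The reference genome is
held in memory as mutable ACGT byte arrays so the simulator can write
sequence features (junction microhomologies, CpG contexts) in place.

## Tumor-only somatic filtering

With no matched normal, somatic status is approximated by three ordered
gates per candidate variant:

1. **Support**: ≥ `min_support` alt reads (default 3; 30 in deep
   targeted-panel mode) *and* VAF ≥ `min_vaf` (default 0.10) in at least
   one sample. Counts are assumed deduplicated upstream.
2. **Cross-sample heterogeneity**: a chi-square goodness-of-fit test of
   the null that every sample shares the pooled VAF
   p̂ = Σalt/Σdepth. Expected alt per sample is p̂·nᵢ, expected ref
   (1−p̂)·nᵢ; df counts only samples with nonzero depth (zero-depth cells
   carry no information and would divide by zero). If p̂ ∈ {0, 1} the
   statistic is defined as 0 and p = 1: heterogeneity is undetectable at
   the boundary. A true somatic variant present in some samples and
   absent in others rejects this null; a germline variant (VAF ≈ 0.5
   everywhere) or a uniform artifact does not. The significance level
   `heterogeneity_alpha` defaults to 0.01 — a deliberately conservative
   choice, configurable, since no canonical threshold exists for this
   design. The test runs across the whole cohort by default, with a
   per-patient-pair mode as an option; cohort-wide is the stricter and
   simpler reading.
3. **Germline database**: exact-allele matching on (chrom, pos, ref,
   alt), not positional, because germline catalogs are allele-specific.

The gate order (support → heterogeneity → germline) is fixed so the
recorded first-failing gate is reproducible; membership of the retained
set itself is order-independent. Monotonicity holds by construction:
tightening support or VAF thresholds can only shrink the retained set.

Type-I calibration of the heterogeneity gate is verified by simulation:
10,000 null variants at VAF 0.3, depth 100, 4 samples flag at a rate
within 3 binomial standard errors of α.

**Trinucleotide spectrum.** SNVs are mapped to 96 classes after
reverse-complement normalization to a pyrimidine (C/T) reference base;
indels, chromosome-edge variants (no flank), and rows whose stated ref
disagrees with the genome are excluded and counted. The class order is
the conventional C>A, C>G, C>T, T>A, T>C, T>G blocks × 16 flank pairs.

## Copy number

Fragments are assigned to fixed windows (default 1 kb) by their start
coordinate — the simplest rule that conserves the total count. The log2
ratio per window is log2((tᵢ/T)/(rᵢ/R)) with T, R the library-size
totals; without this normalization a depth difference between libraries
masquerades as a genome-wide gain. Windows with zero reference coverage
are masked (NaN) and ignored by downstream medians; zero tumor coverage
over covered reference yields −∞, which behaves correctly under medians
and thresholding.

Median decimation reduces consecutive blocks of `factor` windows to
their median (trailing partial blocks use what they have); 200-fold is
the convention for genome-scale tracks, while the simulated toy
chromosomes (hundreds of kb) use factor 10 so that planted events span
multiple decimated windows. Output length is ceil(n/factor) always.

Automatic segment calling replaces the visual read-off of IGV tracks so
recovery is testable: maximal runs within log2-ratio bands, defaults
≤ −3 homozygous deletion, (−3, −0.4] loss, (−0.4, 0.32) neutral,
[0.32, 2) gain, ≥ 2 amplification. These bands are documented test
conventions, not biological claims; they are configurable. Targeted mode
compares per-gene depth to the median of CNA-free baseline regions and
calls only homozygous deletions (≤ −2.5) and amplifications (≥ +2);
intermediate states are deliberately `not_called` because hemizygous
calls are not reliable from panel depth alone.

On simulated pairs at 30×, planted homozygous deletions and
amplifications are recovered with ≤ 1 decimated window of boundary
error, and hemizygous losses average within ±0.15 of −1 at purity 1.
The residual bias comes from library-size renormalization (the tumor
library loses mass in deleted regions and gains it in amplicons) plus
the Jensen bias of log of a Poisson mean; both are small at the default
event sizes.

## Structural variants

Each breakend stores which genomic side survives in the derivative
chromosome (`+` keeps the left/5′ side, junction after `pos`; `-` keeps
the right/3′ side, junction before `pos`), which makes all four
orientation pairs (deletion-like, duplication-like, two inversion types)
unambiguous.

**Filtering** removes junctions with < 5 junction-spanning reads, then
junctions whose breakpoint pair recurs in strictly more than 30 % of
cohort samples — identical somatic breakpoints across patients are
technical artifacts. Breakpoint matching requires *both* breakends
within 200 bp with equal orientations after canonical breakend ordering;
the laxer single-end reading is available behind a flag but chains
unrelated events.

**Clonality**: clonal iff junction AF ≥ 0.2, or spanning-pair AF ≥ 0.2
on both sides (breakend-local depths; span-mean depth is not available
in junction records), or a matched-sample junction lies within the
match radius — a shared truncal event is clonal in both tumors by
definition. Sharing is symmetric.

**Microhomology** is measured against the reference genome at the fused
seam: walking outward from the junction, the retained A-side tail is
compared base-by-base with the reference continuation 5′-ward of B's
retained start (reverse-complemented as the orientations dictate) —
exactly the bases whose assignment to either partner is ambiguous. Runs
shorter than 2 bp report 0; the search stops at 20 bp and flags the
result as censored (longer homology is unknowable by this method, which
is the correct behavior when asking whether homology-directed repair
could have formed the junction). Repair bins: 0–4 bp NHEJ-compatible,
5–18 bp producible only by MMEJ, > 18 bp homology-directed territory.
The implementation is verified against an independent exhaustive
string-comparison oracle on > 1000 randomized junctions covering all
four orientation pairs and planted lengths {0, 2, …, 20}, with 100 %
agreement required.

## TAD integration

Genes are assigned to the TAD containing their transcription start site
(promoter–enhancer insulation is the mechanism of interest; whole-gene
overlap would double-assign boundary-spanning genes). A junction counts
toward a TAD when either breakend falls inside it (a both-ends mode
exists). "Unique to grade 4" means no matched breakpoint pair (200 bp /
orientation rule) in the earlier tumor. The expression gate requires
> 15 raw counts in ≥ 2 samples within either grade group (strict
inequality), and |log2FC| > 1 between matched samples on
counts-per-million with pseudocount 1 — an explicit, self-contained
normalization, since the threshold step needs one and formal
differential expression is out of scope here. A gene is reported when
≥ 2 patients combine an in-TAD grade-4-unique breakend with a
same-direction change; patients showing the change without a
rearrangement are listed alongside, since expression can converge
through other mechanisms.

## Gene-set activity

The all-pairs-correlated subset problem (every retained pair with
Pearson *and* Spearman ≥ 0.4) is a maximum-clique problem; the package
uses greedy worst-offender removal (drop the gene with the most
violating pairs, ties broken lexicographically) for determinism and
O(g²) cost, and every run's output is checked against the brute-force
constraint in tests. Activity per sample is the mean of member z-scores
(each gene standardized across samples on the log2-CPM layer;
zero-variance genes dropped with a warning) times √k — the Stouffer
combined-z convention; a plain-mean mode is available. Scores are
invariant to per-gene positive affine transforms of the normalized
layer and sum to zero across the cohort. Min-max scaling to [0, 1] is
for display only and preserves order; constant inputs map to 0.5 with a
warning.

## Exact statistics

Fisher's exact test orders tables by null probability ("minlike"), the
dominant software convention and the only one that yields p = 1 for
near-symmetric tables; the hypergeometric tail is summed with a 1e−9
relative tolerance so probability ties survive floating point. The
Wilcoxon rank-sum test enumerates the exact rank-sum distribution (a
subset-sum recursion equivalent to enumerating all C(n, n_a)
assignments) when n ≤ 20 and the data are tie-free, doubling the
smaller tail and capping at 1; larger or tied inputs fall back to the
tie-corrected normal approximation and are flagged. Both are validated
against exhaustive-enumeration oracles (all 2×2 tables with N ≤ 12, all
group sizes ≤ 6) and cross-checked against scipy.

## Survival endpoints

Times are integer days from primary surgery. RFS: first reoperation or
death; P4FS: first grade-4 progression (histology at reoperation) or
death; TTP4: progression only, death censors at the death date; OS:
death. Patients with no event and no follow-up end are an error, not a
silent censor. Treatment grouping uses therapy episodes *started*
strictly before the endpoint-defining event or censoring time (start
date rather than end date, because a therapy underway at progression
has plainly been received). Kaplan–Meier estimation and the multi-group
log-rank test are delegated to lifelines.

## The synthetic cohort

The simulator emulates matched grade 2–3 / grade 4 tumor pairs at
desk scale and is the ground truth for every recovery test:

- **Genome**: 2–4 uniform-random ACGT chromosomes of 0.1–2 Mb replace a
  real assembly. All 32 pyrimidine-centered trinucleotide contexts are
  present at these lengths.
- **Events**: the pre tumor carries clonal SNVs and junctions (plus
  configurable subclonal junctions); the post tumor inherits a
  configurable fraction and gains private SNVs, private junctions,
  exactly one homozygous deletion, one hemizygous loss, and optionally
  one high-copy amplification. A hypermutator mode multiplies private
  SNVs and biases them toward CpG C>T. Junction microhomologies are
  planted by writing the retained-side tail into the partner's flank
  for exactly the configured length with a forced mismatch after it.
- **Noise**: binomial allele counts (alt fraction = clone fraction ×
  purity / 2 for heterozygous SNVs; clone fraction for junction
  support), Poisson-Gamma window and expression counts with small
  overdispersion. `noise=0` replaces sampling with rounded expectations
  for zero-noise label-recovery tests. Purity defaults to 1.0 — the
  source setting estimates tumor content histologically but never
  models it numerically, so the knob exists with an arbitrary default.
- **Expression**: negative-binomial counts around lognormal per-gene
  means; member genes of named programs (proliferation +1.5 log2,
  hypoxia +1.0 by default, mirroring the direction of change expected
  at progression) are mean-shifted in post samples.
- **Timelines**: exponential event hazards, Bernoulli therapy
  assignment, a follow-up horizon, and an optional hazard ratio for the
  combination-therapy group. Defaults produce a 75-patient cohort.

What the simulator does *not* emulate — and therefore what passing
tests do not establish about real data: read-level errors and mapping
ambiguity, GC and FFPE biases, subclonal phylogenies beyond a single
clone fraction per event, interactions between event types (an SNV
inside a deleted region still yields reads), gene length and isoform
effects in expression, and calendar-time treatment patterns. The tests
demonstrate correctness of the *computations* under a known generative
model, not performance on sequencing data.

Problem sizes in tests and the acceptance script (3–5 patients, 0.8–2 Mb
genomes, 10,000-variant calibrations) are chosen to exercise every code
path at desk scale; all quantities measured are size-calibrated (rates,
boundary errors in windows, percentages) rather than absolute counts.

## Known limitations

- The heterogeneity test relies on the chi-square approximation; at
  depths ≪ 30 its calibration degrades.
- Library-size normalization of coverage ratios biases all windows
  slightly when a large fraction of the genome is altered; a median- or
  control-region-based normalizer would be preferable for heavily
  rearranged genomes.
- The greedy correlation filter is approximate; it can return a smaller
  set than the true maximum clique.
- Microhomology from reference coordinates cannot see non-templated
  insertions at the seam; junction-consensus sequence would be needed.
- Fisher and rank-sum enumeration are exact only within float summation
  of hypergeometric terms (guarded by a relative tolerance).
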