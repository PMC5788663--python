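# Methods

## Variant tables and the presence matrix

The canonical input is a long-form TSV of per-sample somatic variant
observations (`variant_io.read_variant_table`); a one-sample VCF with
AF/AD/DP FORMAT fields maps onto the same type. Variant identity is
`chrom:pos:ref:alt` (1-based, hg19-style point coordinates as printed in
targeted-panel reports); gene symbol and protein change are annotations
and never part of identity. Copy number is carried as annotation only —
VAFs are the raw read fractions reported by the caller and are not
copy-number corrected.

Filtering follows the targeted-sequencing workflow being reproduced:
variants below a VAF threshold are removed (default 0.05, **inclusive**
— a call at exactly the threshold is retained, since the exclusion rule
is "frequency of less than 0.05"), germline-matched calls are removed by
identity, and optionally synonymous/noncoding consequences are dropped.
The filter is idempotent and order-preserving.

`build_variant_matrix` pivots calls to a variants × samples grid. A
blank cell means *not detected* and is stored as NaN, which is distinct
from a VAF of 0; `present` flags cells with observed VAF ≥ threshold.
Germline samples are excluded from the matrix.

## Trunk/branch phylogeny

`phylogeny.build_tree` implements the classical perfect-phylogeny
reading of a multi-sector presence matrix: distinct carrier sets are
processed largest-first (ties broken lexicographically by variant key,
which the source protocol leaves unspecified); all-sample variants form
the trunk; each smaller set is inserted under the deepest node containing
it, regrouping any children it subsumes; finally every sample terminates
on its own leaf edge carrying its private variants.

Presence patterns that overlap without nesting cannot be placed on any
tree. Such conflicting variants are attached greedily to the edge whose
leaf set is the **largest subset of their carriers** and recorded in a
conflict report — a manual tree-drawing protocol implicitly assumes
nesting, and no error-free guarantee is possible in general. On
conflict-free matrices the output is invariant to row/column permutations
of the input (tested property). Children are ordered by sample label so
samples from the same sector group together; this is cosmetic and never
affects topology. Newick output encodes per-edge variant counts as branch
lengths; round-tripping is verified in tests against an independent
parser (dendropy).

Clone exclusivity uses the cellular-prevalence convention: two
heterozygous mutations occupying complementary clonal populations have
VAFs summing to 1, so `reciprocal_vaf_test` flags a pair exclusive when
|sum − 1| ≤ tolerance (default 0.02, matching two-decimal printed VAFs).
Clone ratios are ratios of mean VAFs over a sample group, with a rounded
"k:1" label; a variant never observed in a group yields NaN, not zero.

Discriminating SNVs between two sample groups are selected by the exact
Fisher test (below) at α = 0.02 (strict `p < α`; α ≥ 1 is treated as "no
filtering" so the degenerate limit returns every variant). Unsupervised
sample clustering uses Jaccard distance on presence vectors with average
linkage — the source protocol names neither; Jaccard is the natural
metric for presence/absence profiles and average linkage avoids the
chaining/compactness extremes. Flat labels come from a 2-cluster cut.

Single-cell colony expectations are Binomial(n, fraction): expected count
and a central exact (Clopper-Pearson-style, via the binomial quantile)
95% interval per genotype.

## Growth model and expansion timing

The model is deliberately minimal: constant doubling time *c*, single
founding cell, no death term (logistic/Gompertz growth and treatment
pharmacodynamics are out of scope). Consequences used throughout:

* Cumulative PDL is linear in time; `fit_doubling_time` regresses it on
  time (OLS with intercept), takes the slope *s* in doublings/day, and
  reports c = 1/s. The 95% CI is the t-distribution interval of *s*
  mapped through the monotone transform s → 1/s, i.e. (1/s_high,
  1/s_low); the source does not state its CI method. A non-positive
  slope (or a slope CI crossing zero) is a fit error. On noiseless
  exponential data the fit recovers *c* to machine precision (tested).
* Tumor cell burden from imaging: N = volume(cm³) × 10¹²(µm³/cm³) /
  cell volume(µm³) × tumor fraction, with defaults 2000 µm³ and 0.5.
* `expansion_onset(N, c, t_obs) = t_obs − c·log₂N` and
  `forward_projection` are exact inverses (tested property).
* The onset-offset bound: if two equally fast clones keep an abundance
  ratio below *r*, the ratio 2^((t+x)/c)/2^(t/c) = 2^(x/c) < r gives
  x < c·log₂r. `derive_onset_offset_bound` performs this solve
  symbolically (sympy) and returns the bound in doubling times — exactly
  2 for r = 4. Onset days are reported to one decimal; window
  comparisons use unrounded values.

Assuming similar doubling times for sibling subclones is justified, in
the emulated study design, by their proportions staying fixed across
passages.

## Alkylator (Signature-11) context classification

Substitution contexts are normalized so the mutated base is the
pyrimidine: for a purine reference the local 3-mer is
reverse-complemented and the strand flag flipped (G>A becomes C>T on the
opposite strand). The classifier calls a variant signature-positive iff
the normalized change is C>T **and** the 3′ neighbor of the central C is
C or T (NpCpC / NpCpT). CpG-context C>T transitions are excluded — they
are the hallmark of spontaneous 5-methylcytosine deamination rather than
alkylation. Indels have no substitution context and are excluded from
both numerator and denominator of signature rates.

Contexts come from either a reference sequence
(`trinucleotide_context`, with reference-mismatch and contig-edge
checks) or a printed annotation such as `"G>A (CCG+)"`
(`parse_printed_context`), where the 3-mer is already pyrimidine-centered
and the sign names the genomic strand carrying it. The ingestion path
trusts printed contexts verbatim after normalization, so annotated
tables are usable without a genome. Normalization is strand-involutive:
extracting from the reverse-complemented reference yields the same
trinucleotide with the strand flag flipped (tested property).

`fisher_exact` implements the two-sided exact test by its hypergeometric
definition — the sum of point probabilities of all same-margin tables
whose probability is at most that of the observed table (relative
tolerance 1e-7) — in exact integer arithmetic, so it agrees with
brute-force enumeration bit-for-bit; tests verify agreement with
enumeration for **all** margins with N ≤ 40 and with scipy. On the
packaged ex vivo tables the classifier yields 15/19 signature-positive
emergent substitutions versus 3/11 pre-existing, with two-sided
p = 0.0086. (The source experiment printed p = 0.0016 for the same 2×2
table; that value is not reproduced by the standard two-sided definition
and its test variant is unstated, so only the counts are asserted.)

### Null calibration of a discrete exact test

Under a zero signature mixture in both groups, the Fisher p-value is
**super-uniform** (P(p ≤ α) ≤ α) and places an atom at p = 1 — both are
structural properties of exact tests on discrete support, so a two-sided
KS test against U(0,1) necessarily rejects even for a perfectly valid
test. The calibration check therefore tests the direction that would
indicate a broken test: a one-sided KS for anti-conservative deviation
(excess of small p-values) plus super-uniformity spot checks at
α ∈ {0.01, 0.05, 0.1}.

## Regulatory model

**Affinity.** `promoter_affinity` scores a PWM over an accessible
cis-window as the sum, over all sliding positions on both strands, of the
likelihood ratio against a uniform 0.25 background — a TRAP-like soft
count rather than thresholded hits. A summed score keeps the downstream
regression well-posed; sites touching a masked (inaccessible) position
contribute nothing, ambiguous bases score as background, and the score is
additive over disjoint accessible segments (tested against a brute-force
per-position scorer). PWMs are column-stochastic after pseudocount
normalization (default 0.5); JASPAR count files are parsed via Biopython.

**TF activity.** For each sample, genome-wide expression is regressed
across genes on the TF's affinity vector (simple OLS **with intercept**;
the source phrasing is ambiguous between per-sample-across-genes and
per-gene-across-samples, and the per-sample reading is taken literally).
The slope is the TF's activity in that sample. Activities are equivariant
to per-sample affine rescaling of expression (slopes rescale
accordingly). Zero-variance affinity vectors yield no activity.

**Window selection.** Affinities are computed for windows of 1–10 kb;
for each size, high-affinity genes (top decile) are intersected with
genes whose expression correlates with the inferred activity
(Benjamini–Hochberg FDR < 0.05 across genes), the overlap is scored by
hypergeometric enrichment, and the size with the smallest enrichment p
wins, ties to the smaller window. The enrichment criterion and threshold
are not stated by the source protocol; both are exposed as parameters
(defaults: top decile, FDR 0.05, selection requires p ≤ 0.05 — pure-noise
inputs are flagged unselected).

**Targets and miRNA activity.** Functional TF targets are the
intersection of top-decile affinity genes and FDR-significant correlated
genes. miRNA activity is the per-sample OLS slope on the binary
target-membership indicator — algebraically the mean expression
difference targets minus non-targets, so active repressors score
negative. miRNAs with fewer than 100 targets among the expression genes
are dropped for robustness.

**Key-driver analysis.** Candidates are the signature genes plus all
nodes within `neighborhood_depth` steps (direction ignored while
gathering candidates; default depth 2, consistent with small h-layer
neighborhoods in key-driver methodology). Each candidate's downstream
set is everything reachable within depth **directed** hops; its
enrichment p is the hypergeometric upper tail of the downstream overlap
with the signature against all network nodes, and the adjusted p is
Bonferroni over candidates (min(1, p × n_candidates), chosen because the
emulated report's adjusted/raw ratios are a constant equal to the
candidate count). Ranking is by p, then downstream size descending, then
name. Full-scale causal-network reconstruction from cohort data is out of
scope — any user-supplied directed edge list is accepted instead, so
cohort-specific driver identities are not reproduced here.

## Synthetic data: what it does and does not emulate

All generators take an integer seed and are byte-deterministic; each
returns a truth record sufficient to score the downstream operation.

* **Clonal sequencing** (`simulate_clonal_sequencing`): expected allele
  VAF of a variant in a sector is Σ_clones carrying it fraction ×
  het_dosage/ploidy; depth is drawn per site from a negative binomial
  around the mean (default 2000×, dispersion 20 — avoids unrealistically
  uniform coverage) and alt reads are binomial. Defaults mirror the
  emulated sector structure: a trunk plus two mutually exclusive
  subclones at 2:1 (two sectors) and 3:1 (one sector), three private
  markers per clone. Reporting offers the raw allele fraction (with read
  counts) or the cellular-prevalence convention (×ploidy/het_dosage,
  capped at 1) under which exclusive heterozygous clones sum to ~1.00;
  prevalence is the default because that is the convention of the grids
  being emulated.
* **Growth** (`simulate_growth`): cumulative PDL = (t − t_onset)/c +
  N(0, σ) at 3.5-day passages over 70 days (default c = 2.24 d,
  σ = 0.2), converted to seeded/harvested counts; negative increments are
  clipped to zero growth with a warning.
* **Genome and mutations** (`simulate_genome_and_mutations`): a uniform
  random genome (default 20 kb, GC 0.5); emergent mutations are drawn
  from the signature channel (C>T at a site whose pyrimidine-strand 3′
  neighbor is C/T, either strand) with probability `signature_mixture`
  (default 0.8) and uniformly otherwise; pre-existing mutations are
  uniform. Background draws can land in signature contexts by chance, so
  the classified fraction sits slightly above the mixture — the recovery
  test allows for this.
* **Regulatory model** (`simulate_regulatory_data`): expression =
  affinityᵀ × activity − miRNA repression + N(0, 0.5) over 2000 genes ×
  20 samples; each TF has a disjoint 100-gene high-affinity block
  (U(2,4)) and near-zero baseline elsewhere (U(0,0.05)), reflecting
  promoters lacking the motif; miRNA repressors hit 150-gene blocks with
  per-sample strengths U(0.5,1.5). `simulate_driver_network` plants two
  drivers over disjoint 30-gene modules on a random directed background.

The generators emulate the *statistical structure* the analyses assume —
binomial read sampling, log-linear growth, context-biased mutagenesis,
linear-Gaussian regulation. They do **not** emulate sequencing error or
strand bias, copy-number-distorted VAFs, subclonal copy number, cell
death or treatment pharmacodynamics, RNA-seq count noise, or realistic
promoter sequence composition. Passing recovery tests therefore
demonstrates correctness of the estimators under their stated model, not
robustness to those real-data violations.

## Problem sizes and test design

The test suite runs the stochastic recovery properties at sizes chosen to
make Monte-Carlo error small relative to the asserted bounds on a single
CPU in minutes: 200 seeds for median doubling-time recovery (1000 for
interval-coverage calibration, where 200 replicates would leave ~1.5%
Monte-Carlo noise against a 93% bound), 500 seeds for ratio recovery and
null calibration, 100 network rewirings for driver ranking, and
exhaustive Fisher enumeration for all table margins N ≤ 40. Fixed seeds
make every test deterministic; hypothesis property tests run
derandomized.

## Known limitations

* The tree builder assumes presence/absence at a single threshold;
  probabilistic clone deconvolution (CCF clustering) and copy-number
  inference are out of scope (copy-number events can be supplied as
  pseudo-variants with presence flags).
* Onset dating inherits every assumption of the single-founder
  constant-rate model; reported onset days are point estimates without
  propagation of the doubling-time CI.
* The signature classifier is a two-channel rule (alkylator context vs
  everything else), not a 96-channel signature decomposition; it cannot
  separate alkylator transitions from deamination at non-CpG sites.
* TF activities are identifiable only up to the scale of the affinity
  vector; comparisons are meaningful within a TF across samples.
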