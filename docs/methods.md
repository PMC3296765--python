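# Methods

## Problem setting

Comparing gene expression across diverged species with RNA-Seq confounds
four sources of variation: genuine inter-species expression differences,
environmental response between cultures, technical imprecision of library
preparation and sequencing, and Poisson counting noise. In closely
controlled yeast experiments the environmental component alone can rival
the evolutionary signal, so a test that treats counts as Poisson (or that
scales samples by total read count) badly over-calls differential
expression. divseq models each count's variance explicitly and calibrates
the model on replicates, where the null hypothesis is true for every gene.

All analyses operate on raw unique-read counts. Counts are never
length-normalized: the Poisson component of a measurement's variance is a
function of the raw count, and rescaling destroys that information.

## The test statistic

For counts `C_g`, `T_g` in two samples, the statistic is

    X² = (C_g − μ_C)² / [μ_C + (σ_C μ_C)²] + (T_g − μ_T)² / [μ_T + (σ_T μ_T)²]

**Null means.** Samples differ in depth, so separate means proportional to
depth are needed. The scaling slope `m` is the median of per-gene
test/control ratios over genes present in both samples with a nonzero
control count; a median is immune to the handful of highly expressed
outlier genes that can dominate total-count ratios. The means project the
observed pair onto the line `y = m·x`: `μ_C = (C_g + T_g/m)/2`,
`μ_T = (C_g·m + T_g)/2`. Both samples get equal weight regardless of depth
and the raw counts themselves are never rescaled. Genes with
`μ_C = μ_T = 0` return `X² = 0` (p = 1).

**Variance composition.** Poisson and non-Poisson variance are independent,
so they add: `σ²(μ) = μ + (σ_nP·μ)²`, with `σ_nP` a *relative* SD. This
composition is used identically in the statistic, the calibration, the
fold-change intervals, and the simulator.

**Degrees of freedom.** Two terms are summed, but the common mean was
estimated from the same two observations, so the statistic is referred to
χ² with one degree of freedom. Under simulation from the null with the true
σ supplied, the statistic's sample mean is ≈ 0.98 at n = 10,000 — close to,
and slightly below, the χ²(1) mean of 1. The shortfall is real: the
denominator is evaluated at the *estimated* mean, which (by convexity of
μ ↦ (σμ)²) slightly over-states the variance on average, more so at large
σ. The test is therefore mildly conservative, which we prefer to the
alternative bias.

## The variance model

Per gene and species, a biological replicate pair gives
`R = mean(counts)`, `σ²_reps = sample variance (n−1)`, and

    σ_m = sqrt(max(0, σ²_reps − R)) / R

The clamp at zero handles the many genes whose two replicates agree by
chance. Sample variance uses the n−1 denominator (unbiased at n = 2).

Gene function is conserved across these species, so gene-specific variance
is assumed shared: per-species estimates are pooled by a weighted mean with
weights `R` (more reads ⇒ less Poisson contamination of the estimate).
Estimates with `R < 30` are discarded as Poisson-dominated; if none survive
for a gene, its σ falls back to the species-level uniform `U` (applied
directly, without flooring or rescaling). Pooled values are floored by the
technical resolution `σ_t` and, when used in a test involving species `s`,
rescaled by `U_s / mean(U)` to reflect how well that species' replicates
reproduced.

**Calibrating U.** In a replicate self-comparison every DE call is false,
so a uniform relative SD can be tuned until the false-call rate matches
the nominal level: `U` is the smallest value at which the number of genes
with p < α is at most α times the number of eligible genes (mean count
≥ 10; lower counts are Poisson-dominated and would skew the calibration).
Because every gene's statistic is non-increasing in `U`, the count is
monotone and the minimal `U` is found by bisection on a grid over
[0, 2] with step 0.001 — exact to grid resolution. Exact equality of the
DE fraction and α is unattainable with discrete counts, hence the
"at most" form. If the data are underdispersed even at `U = 0` the
calibration returns 0 with a flag. `σ_t` is itself a `U` calibrated on a
technical replicate pair restricted to coding genes; 0.16 is the package
default for deeply sequenced yeast libraries.

Calibration accuracy is bounded by two effects worth knowing about. The
false-call count at the true `U` is binomial (SD ≈ 22 genes at n = 10,000,
α = 0.05), which maps to roughly ±0.003 in the calibrated value. And
because the statistic is mildly conservative under multiplicative
(log-normal) noise — increasingly so as σ grows — the calibrated `U`
under-shoots a large planted over-dispersion by several percent (about 8%
at σ = 0.3). Both effects are properties of the method, not of the search.

## Batch pairing and combined tests

Cultures grown on different days share day effects that masquerade as DE.
Comparisons are therefore restricted to same-batch pairs (Rep1 vs Rep1,
Rep2 vs Rep2), treated as independent tests, and combined with Fisher's
method (−2Σln p ~ χ² with 2k DF). A gene is called DE when the combined p
falls below α (default 0.01). No further multiple-testing correction is
applied — the calibration already anchors the per-gene false-call rate —
but the companion FDR estimate (replicate DE fraction × genes tested /
genes called) summarizes the expected false discovery burden. Genes whose
mean count in a batch falls below 10 reads are tested but flagged
`low_count`: for them only large fold changes are detectable.

## Fold changes and confidence intervals

Fold changes divide counts normalized to a common library size (the
geometric mean of the two totals by default; fold changes are invariant to
this choice). The SD of the log2 fold change propagates each normalized
count's composed variance:

    σ_FC = sqrt( σ²(T)/(T·ln2)² + σ²(C)/(C·ln2)² )

with ±2σ as the ≈95% interval. Zero counts leave the ratio undefined; such
genes carry NA intervals rather than pseudocounts. The result table reports
the first batch's fold change (a single coherent pair) plus the
across-batch mean, which drives direction calls downstream.

## Inclusion criteria

Cross-species count comparisons are only meaningful for genes whose
annotations are equivalent in both species. A gene (keyed by its
reference-species ID) is *measurable* in a species when it has exactly one
ortholog there, the ORF is complete, the annotated length is within
90–110% of the reference length (inclusive; the source is ambiguous at the
endpoints), at least 90% of its aligned reads align uniquely, and it is
protein-coding (non-coding RNAs reproduce poorly even in technical
replicates). *Core* genes are measurable in every species and are the gene
set for all multi-species analyses. Duplication candidates require exactly
two orthologs in the target species, each covering > 60% of the reference
gene; coverage is an input (alignment is upstream of this package) and
further screening hooks in as a pluggable predicate.

## Evolutionary analyses

**Lineage assignment.** Over the fixed four-taxon topology
((cerevisiae, paradoxus), (mikatae, bayanus)), a gene is assigned to a
branch iff every species pair split by that branch is significant at α
(combined p) with fold changes all pointing the same way; direction uses
the sign of the across-batch mean log2 FC. Terminal branches require 3
consistent pairs, the internal branch all 4 cross-split pairs. Genes may
be assigned to several branches (multiple independent changes).

**Divergence clock.** For each comparison (including replicate self-pairs
at distance 0) the variance of defined log2 fold changes is regressed by
OLS on the intergenic substitution rate separating the samples. Slope =
expression divergence rate; intercept = replicate (zero-divergence)
variance. Genes with undefined FC are excluded, not imputed. Gene-class
slopes are compared by analysis of covariance (p-value of the class × rate
interaction). The canonical substitution rates for the four yeasts
(0.231–0.556) ship as a constant.

**Clustering.** Samples are clustered hierarchically (average linkage; the
linkage choice is an open design point fixed here) on 1 − Spearman
correlation of core-gene expression; rank correlation makes the tree
invariant to monotone transforms of expression.

**Paralog contrast.** Each copy of a duplicated gene is tested against the
single reference ortholog with the same χ² machinery (α = 0.01) and
classified consistent / significantly below / significantly above; the
more sequence-diverged copy is named by an upstream phylogenetic analysis
and consumed as input.

## Simulator

The generator mirrors the method's own assumptions: per-gene means
log-normal (log-mean 5, log-sd 1.5: counts from ~10 to ~10⁴, >95% of genes
above 10 reads — the regime of a deeply sequenced yeast library), latent
multiplicative expression noise that is log-normal with mean 1 and CV σ_g
(expression varies multiplicatively), Poisson sampling on top, two same-day
batches per species, default uniform σ = 0.16. Over-dispersion may instead
vary per gene (log-normal around a median). DE effects apply to one
species' means as fixed log2 shifts, normal draws, or Cohen's D multiples
of the gene's null log2-FC SD, so an effect of d = 3 is equally detectable
at any depth.

What the simulator does *not* emulate: gene-length effects, mappability
differences, correlated gene modules (co-regulation), batch effects with
structure beyond independent replicate draws, and annotation error. Passing
simulation-based tests therefore demonstrates the statistical engine's
calibration under its own assumptions, not robustness to every artifact of
real cross-species data — the inclusion criteria exist precisely to keep
those artifacts out of the tested gene set.

For CI-coverage experiments the two samples are put on a common scale via
the median-ratio slope split symmetrically (C·√m, T/√m) rather than by
total counts: with many genes shifted, totals are biased by the mean of
2^shift while the per-gene ratio median is not.

## Numerical choices and limitations

- Minimal-U search: grid [0, 2] step 0.001, monotone bisection; returns the
  boundary with a flag when the target is met at 0 or missed at 2.
- Negative non-Poisson variance estimates clamp to 0 before flooring.
- Zero-count genes: X² = 0, p = 1, NA fold change; no pseudocounts anywhere.
- Even-length ratio lists: the median is the mean of the two central values.
- Species U values are kept ≥ 10⁻⁶ so rescaling ratios stay defined for
  degenerate (identical-replicate) inputs.
- Problem sizes in the test suite and acceptance experiments (10,000-gene
  calibrations, 5,000-gene coverage runs, 3 seeds) are chosen so each
  experiment's Monte-Carlo error is small relative to the tolerance being
  checked while a full run stays interactive on one core.
- With only two replicates per species, per-gene variance estimates are
  noisy even after pooling; the floor and the fallback to U are what keep
  the test's false-positive rate near nominal, at the cost of mild
  conservatism for genuinely low-variance genes and slight anti-conservatism
  when many genes' true σ exceeds the floor.
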