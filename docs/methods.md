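# Methods

## Model and procedure

The package treats regional expression as a one-dimensional signal per
chromosome: genes are the sampling points (ordered by integer midpoint
`⌊(start + end)/2⌋`, ties broken by start then gene id), and the
per-gene value is either the median log2 expression across a tissue
panel (the combined map) or a single tissue's value.  Smoothing is a
running median over a fixed *gene count* — not base pairs — so
gene-dense and gene-poor chromosomes are smoothed with comparable
statistical support.  The default window is 39 genes; strand-separated
maps use 19 because each strand holds roughly half the genes.

Region calling compares the smoothed values against multiples of the
*genomic median* `M`, the median of all analyzed genes' raw
(unsmoothed) summary values.  A RIDGE is a maximal run of ≥ `min_run`
(default 10) consecutive genes with smoothed value strictly above
`r·M` (default `r = 1.19`); an anti-RIDGE the converse strictly below
`a·M` (default `a = 0.78`).  Values exactly at a threshold qualify for
neither class.  Runs never cross chromosome boundaries, and two
qualifying runs separated by a single non-qualifying gene remain two
regions — no merging, which is the literal reading of "consecutive
running medians".  A region's genomic span runs from its first member
gene's start to its last member's end; when a long straggler gene in
one run reaches past the start of the next same-kind run, the earlier
span is clipped at the later region's start so that same-kind coverage
stays additive (member genes then always keep their *midpoints* inside
the span, though an extreme gene's tail may extend past it).

Because the multipliers are scale-relative (1.19 × a genomic median of
~7 log2 units is a ~1.3-log2 absolute offset), the caller can instead
calibrate them: coverage is monotone in each multiplier (non-increasing
for RIDGEs, non-decreasing for anti-RIDGEs), so 60 bisection steps over
[1, 3] and [0.1, 1] find the multiplier whose achieved coverage is
closest to a target (default target 0.10, the coverage the original
thresholds were chosen to produce).  Coverage is a step function of the
multiplier, so the closest *visited* value is returned together with
the achieved coverage and a warning flag when the best achievable
coverage is more than one percentage point from the target.

### Coverage denominator

A chromosome's analyzed extent runs from its first gene's start to its
last gene's end, and the genome length used for coverage (and for
breakpoint-enrichment expectations) is the sum of these extents, not
the assembly length; annotation-free telomeric stretches carry no
evidence either way.

### Permutation null

The test statistic is the RIDGE count.  Under the null of no spatial
organisation, the assignment of expression values to gene positions is
exchangeable, so each replicate shuffles the value multiset over the
fixed positions genome-wide (values may move between chromosomes),
re-smooths and re-calls at fixed thresholds.  The genomic median is
permutation-invariant, so thresholds need computing once.  If the
caller configuration requests coverage calibration, calibration runs
once on the observed map and the resulting multipliers are frozen for
all replicates — per-replicate recalibration would pin every
replicate's coverage to the target and destroy the test.  The reported
p is the strict-greater fraction `#{null > observed}/n`; a
`conservative` flag switches to `(k+1)/(n+1)`.

The strict-counting p is discrete, and ties between null counts and the
observed count bias it low (on structure-free genomes its mean over
seeds sits near 0.41 rather than 0.50 at `n_perm = 200`).  This is a
known artifact of discrete permutation p-values, not a miscalibration
of the null: after standard randomized tie-breaking,
`(#{null > obs} + U·(1 + #{null = obs}))/(n + 1)` with `U ~ Uniform(0,1)`,
the p-values over 100 independent null genomes pass a
Kolmogorov–Smirnov uniformity test comfortably.  The calibration test
in the suite applies exactly that correction and separately checks the
strict p's mean; all reported p-values elsewhere use the strict rule.

### Feature tracks

Per-gene features are aligned 1:1 with the map's gene ordering and
smoothed with the same window before correlation.  Window-based
densities (genes per 100 kb; 50–150 bp "minimal" introns per 500 kb)
center the window on each gene's midpoint, clip it to the chromosome's
analyzed extent and rescale the count to the nominal width — a gene
10 kb from the chromosome start sees a 60-kb window and its count is
scaled by 100/60.  The window includes the query gene itself, so on
sparse genomes the mean density overestimates the global rate by
~1 gene/window; density-integration checks therefore use gene-dense
test genomes.  Average intron length is the mean over transcripts of
each transcript's mean intron length; intronless genes are *missing*,
not zero — zero would conflate absence with shortness — and are
excluded from rank tests and interpolated over (linearly, in gene-rank
space) when a smoothed track needs a complete series.

Map-vs-track association uses Spearman rank correlation on the
smoothed series (the smoothed values are far from normal), with the
large-sample p-value by default and a seeded Monte-Carlo permutation p
behind a flag for short series.  Note that smoothing induces strong
short-range autocorrelation, so the nominal p-values overstate
independence; the package reports them as the field conventionally
does, and the tests rely on signs and magnitudes rather than the
p-values of these correlations.  The per-chromosome median-expression
vs length relationship uses Pearson correlation.  Region-class
comparisons (RIDGE vs anti-RIDGE vs genome) use the two-sided Wilcoxon
rank-sum test.

### Synteny breakpoints and homologs

Every synteny block contributes its two ends as breakpoints, each
located in both genomes; a `-` block pairs its left A end with its
right B end.  Breakpoint-in-region membership is point-in-half-open
interval; gene-in-region membership uses the gene midpoint (consistent
with map ordering), with whole-gene and any-overlap rules behind a
flag.  Enrichment is a 1-df chi-square goodness of fit of the (inside,
outside) counts against (f, 1−f), f the regions' genome fraction,
without continuity correction (the counts involved are large).
Cross-species classification labels each breakpoint by region kind on
both sides; the RIDGE-to-RIDGE count is tested against the
independence expectation `n·f_A·f_B` with empirical marginal
fractions.  Homolog conservation asks: of 1-to-1 pairs whose A gene
lies in an A-RIDGE, what fraction's B gene lies in a B-RIDGE, compared
with the fraction of all B genes in B-RIDGEs.

## The synthetic generator

`SimulationConfig` defaults describe the study conditions the pipeline
assumes, scaled to run fast: 10 chromosomes with lengths log-uniform on
10–40 Mb (so sizes vary ~4-fold), genes by a Poisson process at
22 genes/Mb (~5,000 genes), 8 tissues, planted non-overlapping "high"
and "low" blocks each covering ~10% of every chromosome (per-block
sizes jittered ±30%, separated by at least one smoothing window of
expected genes so ground truth is unambiguous), expression
`baseline + regime shift + gene effect + tissue effect` with baseline
7.3 log2 units (the intensity scale of two-colour arrays), shifts
±0.8 log2, per-gene scatter SD 0.5 and per-tissue scatter SD 0.3.
Feature coupling inside high blocks: GC +0.05, gene-length and
intron-length scale ×0.55, gene density ×1.6 (low blocks: −0.03,
×1.6, ×0.7).  `SimulationConfig.full_scale()` emits ~11,400 genes on
27 chromosomes (2–200 Mb) for full-scale runs.

The rearranged second genome is produced by cutting genome A only at
inter-gene gaps (candidate cuts are the gaps between
midpoint-consecutive genes, so no gene is ever split), sampling 200
cuts with weight `breakpoint_ridge_bias` (default 2.5) for gaps inside
high blocks, then shuffling, randomly inverting and concatenating the
segments into genome-B chromosomes.  Every A gene maps to exactly one
B gene; homologs inherit genome-A expression, which lets region
calling run properly on both genomes.  Planted intervals are carried
through the rearrangement into genome B's ground truth.

Randomness uses one global seed feeding a named stream per component
(genome, expression, synteny), so extending one component's draws never
perturbs the others.

What the generator does *not* emulate: probe-level microarray noise and
normalisation artifacts, missing expression values, chromosome-size
gradients in expression or GC (no macro/micro-chromosome trend is
planted by default — the length-correlation machinery is exercised
with an explicitly planted offset in the tests), overlapping or nested
gene models beyond what Poisson placement produces, and realistic
rearrangement size distributions.  Passing tests therefore demonstrate
that the algorithms recover the structure they target under clean,
known conditions; they do not certify performance on array data with
correlated technical noise.

## Numerical choices and edge rules

- Running-median edges: at position `i` the largest odd window centred
  on `i` that fits is used ("shrink"), so the first and last genes keep
  their raw values; the classical "keep" end rule is available.  The
  choice only affects `(w−1)/2` genes per chromosome end.
- Chromosomes retaining fewer genes than the smoothing window are
  excluded with a warning (mirroring the exclusion of very gene-poor
  chromosomes from full-scale analyses); the minimum is configurable.
- Duplicate-coordinate genes are retained on adjacent ranks; ordering
  ties break deterministically by (midpoint, start, gene id).
- Internal coordinates are 0-based half-open everywhere; TSV/GFF
  inputs (1-based inclusive) are converted on read and restored on
  write, BED passes through.
- Probe collapsing averages a gene's probes per tissue; probes mapping
  to no gene or to more than one gene are dropped and counted, and an
  exactly duplicated probe-map row is an error (it signals a corrupt
  annotation rather than genuine multi-mapping).
- Calibration search: 60 bisection iterations, brackets [1, 3] and
  [0.1, 1], deterministic given the map.

## Known limitations

- The permutation test treats genes as exchangeable units and ignores
  per-chromosome value conservation ("throughout the genome"
  shuffling); chromosome-stratified shuffling would be a stricter null
  for chromosome-level expression differences.
- Smoothed-series correlations inherit window-induced autocorrelation;
  their asymptotic p-values are optimistic (see above).
- Region extents derive from member-gene bounds; alternatives (e.g.
  smoothing-window bounds) would shift coverage by fractions of a
  window at each region edge.
- The breakpoint count is exactly twice the block count; lifted-over
  real data may lose unmappable ends, so observed totals can fall
  short of `2 × blocks`.
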