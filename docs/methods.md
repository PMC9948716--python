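# Methods

## Study design assumed by the pipeline

Two strains are compared: `stressA`, in which ribosome assembly is blocked
(nucleolar stress) while existing ribosomes keep translating, and
`stressB`, in which ribosome function is progressively inhibited
(translation stress) without changing ribosome numbers. Each strain is
sampled in replicate before the shift that induces stress (control) and at
three post-shift times (early, middle, late) chosen at matched growth
rates. Every contrast in the package is a post-shift time class against
the same-strain control, so strain-specific baseline differences cancel
within strain, and the cross-strain control ratio is reported separately
(the first heatmap column) as a baseline-comparability check.

## Normalization and gene universe

Size factors are the median-of-ratios estimator: for sample *s*,
`sf_s = median over reference genes g of counts[g,s] / geomean_g`, where
the reference genes are those with positive counts in every sample and
`geomean_g` is the gene's geometric mean across samples. The median is
taken in log space; for an odd number of reference genes this is the plain
median of ratios, for an even number it is the geometric rather than
arithmetic mean of the two central ratios (the convention of the standard
Python implementation of this estimator, against which the package is
cross-checked in the test suite). Size factors are computed on the full
matrix before any gene filtering.

The analysis universe keeps genes whose replicate-mean **raw** count is at
least `min_count` (default 50) in each of the eight strain × time cells.
The replicate mean, rather than the per-replicate minimum, is used because
the rule is a floor on average sequencing support per condition. All
downstream tables — differential expression, DEG summaries, RVD ranks,
baseline ratios — are computed on this filtered universe.

PCA for sample QC operates on log2(normalized + 1) with per-gene centering
and no per-gene scaling, using all retained genes. The log transform keeps
the handful of most abundant transcripts from dominating the rotation;
whether to log-transform is an explicit configuration choice, not an
inference about how any particular published analysis did it.

## Differential expression

Per gene, strain and time: `lfc = log2((m_t + c)/(m_0 + c))` with
replicate-mean normalized counts *m* and pseudocount `c = 0.5` (finite lfc
at zero counts; configurable). Significance comes from a two-sample t test
on log2(normalized + c) replicate values, time group versus control within
strain. The default is the pooled-variance (Student) test. The Welch
unequal-variance test is available (`var_policy="welch"`) but is not the
default: with three replicates per group the Satterthwaite approximation
is intrinsically conservative — in simulation its rejection rate at
nominal alpha = 0.05 is ~0.033 even on exactly normal data — whereas the
pooled test holds the nominal level almost exactly in the generator's
regime (~0.050 measured on filtered null NB counts). At equal group sizes
and approximately equal variances, which the log transform of moderately
dispersed counts delivers, the pooled test is also the more powerful
defined test. Degenerate-variance guard (reachable with three integer-ish
replicates): when both groups have zero variance, p = 1 for equal means
and the smallest positive float otherwise.

Benjamini–Hochberg adjustment is applied within each strain × time
contrast separately (six families), matching the per-sample reporting unit
of the DEG lists. A gene is a DEG when |lfc| ≥ 1 (inclusive) and
FDR < 0.05 (strict).

The overlap summary counts, per time and for total/up/down blocks,
strainA-only, both-strain, and strainB-only DEGs, the union, and each as a
percentage of the universe rounded to one decimal; a "persistent" row
counts genes that are DEGs at all three times within a strain. A gene
called up in one strain and down in the other at the same time counts in
the "both" column of the total block, in neither directional both-column,
and per its own direction in the strain-only columns; the per-time count
of such discordant genes is reported alongside so the convention is
auditable. This convention preserves exact additivity
(union = A-only + both + B-only in every block).

Trend analysis: Δlfc = lfc(late) − lfc(early) per gene and strain;
selection at |Δlfc| ≥ 1. Genes responding to the medium shift alone settle
within the early window (Δlfc ≈ 0); genes responding to the accumulating
stress keep moving.

## RVD scoring

Within each strain × time, genes are ranked by lfc ascending (rank 1 =
most repressed) with average ranks for ties; ranking by raw fold change
would give identical ranks since log2 is monotone. Ascending order is a
convention only — the absolute rank-sum used for selection is invariant to
reversing rank direction, and the direction is recorded in output
metadata. Average ties keep the per-time RVDs summing to zero across
genes, which the property suite exploits.

`RVD_t = rank_A,t − rank_B,t`; `abs_rank_sum = Σ_t |RVD_t|`;
`rank_sum = Σ_t RVD_t`; `rank_sign = abs_rank_sum − rank_sum` by default.
The phrase defining the rank sign admits a second algebraic reading,
`|rank_sum| − rank_sum`, which is implemented behind
`rank_sign_variant="abs_of_sum"`; both are exposed rather than silently
choosing one. Extreme-gene selection (the "most/least differently
regulated" lists, default k = 200) sorts by abs_rank_sum with a
deterministic lexical tie-break on gene id.

## Paralogue ratios

For each A/B pair, strain and time:
`log2_ratio = log2[(A_t/B_t)/(A_0/B_0)]` from replicate-mean normalized
counts with pseudocount. Mean-first (rather than averaging per-replicate
ratios) is stable at low counts; a per-replicate variant would only be
needed for uncertainty estimates, which the flag rule does not use.
Normalizing to the control ratio cancels any allele-specific
capture/mapping efficiency, which also means absolute A:B expression
ratios are out of scope by construction. A pair is flagged when
|log2_ratio| ≥ log2(2.5) at any strain × time (inclusive). Pairs with a
member excluded by the min-count filter are reported as not evaluable,
never silently dropped.

## Gene-set enrichment and mass fractions

Over-representation is the hypergeometric upper tail
P(X ≥ overlap) with fold enrichment (overlap/query)/(set/universe), BH
across tested sets; sets with fewer than three members after intersection
with the universe are reported untested. Only over-representation is
computed. Class mRNA-mass fractions are sums of replicate-mean normalized
counts over set members divided by the sum over all genes, per strain at a
chosen time; the ratio of sums makes them invariant to size-factor
rescaling.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes and
is itself first-class, tested code. Defaults:

- 5,000 genes; 3 replicates; one strainB middle replicate dropped
  (23 samples), mirroring a design in which one RNA sample failed QC.
- Baseline abundances log-normal(log 400, sd 1.2), tuned so ~90–95% of
  genes clear the 50-count filter; per-sample library factors
  log-normal(0, 0.15).
- Negative-binomial counts with mean = baseline × 2^lfc × library factor
  and size 80 (variance = μ + μ²/80, per-replicate CV ≈ 0.12 at high
  counts). The size was fixed by a design-stage power analysis: with three
  replicates, recovering a planted lfc −1.5 as a down-DEG in *both*
  strains at ≥ 90% requires the observed lfc itself to clear −1 in each
  strain, which bounds the usable per-replicate CV near 0.15; size 80 sits
  inside that bound and within the dispersion range of tightly controlled
  yeast culture triplicates. A much noisier setting (e.g. size 10,
  CV ≈ 0.32) makes that recovery impossible for any test, since the
  |lfc| ≥ 1 threshold alone then rejects ~10% of true effects per strain.
  `dispersion=None` (or infinity) switches to Poisson draws.
- Planted classes: `concordant_down` (15%, lfc −1.5/−1.6/−1.6 in both
  strains — the glucose-repression signature: established early, stable
  after), `opposite_trend` (10%, strainA −0.5/+0.3/+1.0 vs strainB
  +0.5/−0.5/−1.5 — the r-protein signature: repression-then-induction
  under the assembly block, shift-up induction-then-repression under the
  function block), `flat` (10%) and `null` (remainder), plus 60 A/B
  paralogue pairs of which 15% are shifted: the A member gains +2.0 lfc at
  middle/late in strainA, a 4-fold A:B ratio shift, comfortably past the
  2.5-fold flag and chosen to represent the clearly-shifted pairs rather
  than borderline ones.
- Paralogue-pair genes draw baselines from log-normal(log 2000, sd 0.5):
  their real analogues (r-protein transcripts) are abundant — the class
  carries ~20% of mRNA mass — and span a far narrower dynamic range than
  the transcriptome at large. This keeps pairs above the count filter, as
  they are in real data.
- One seed feeds three independent child streams (truth, library factors,
  counts), so toggling library jitter does not reshuffle the planted
  classes.

What the generator does **not** emulate: gene-gene correlation, mean-
dependent dispersion trends, batch structure, length/GC bias, discrete
time-course kinetics of the shift-up (only its lfc signature is planted).
Passing recovery tests therefore demonstrates that the pipeline's
arithmetic and decision rules recover planted structure under idealized
independent NB noise — not that any particular biological dataset would
yield the same lists.

## Problem sizes and numerical choices

Test and verification runs use the default 5,000-gene fixture and a
6,000-gene null simulation (24 samples, 3v3 contrasts), sizes at which
every recovery and calibration metric is stable across seeds. Type-I
error is judged against ± 2 Monte-Carlo standard errors of alpha at the
realized post-filter gene count. Ranking ties use average ranks
everywhere; ordering ties in sorted outputs break lexically by gene id;
percentages are rounded to one decimal at the reporting boundary only.
0/0 baseline ratios are undefined and excluded from the band fraction;
x/0 is +infinity and counts as outside the band.

## Known limitations

- The t test on log-transformed normalized counts is a deliberate,
  self-contained substitute for a negative-binomial GLM; it does not
  reproduce NB-Wald p-values, and at very low counts (means near the
  filter floor) the log-scale normal approximation weakens. The testing
  step is isolated behind one function so an NB-GLM variant can be added.
- No lfc shrinkage, dispersion sharing across genes, or time-course
  (spline) modeling; contrasts are independent two-group comparisons.
- Enrichment treats gene sets as flat lists; no ontology topology or
  parent–child propagation.
- The 23-sample dropout leaves one contrast at 2 vs 3 replicates, where
  the pooled t is at its weakest; results for that single cell carry
  wider error than the others.
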