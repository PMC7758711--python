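# Methods notes

This note records the statistical models the package implements, the
assumptions and defaults of the synthetic-data generator, the numerical
choices that were genuinely open, and known limitations. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The factorial model and RRPP

The phenotype table pivots to an n × p response matrix Y (p substrates),
with crossed categorical factors treatment and time (transfer). Time is
categorical, not continuous: a trajectory is the ordered sequence of
per-transfer least-squares means, so no functional form over time is
assumed. Models are fit by ordinary least squares per response column;
multivariate sums of squares are traces of cross-product matrices of
projection differences, entered sequentially (treatment, then time, then
interaction). On balanced designs all entry orders agree; unbalanced inputs
get a warning rather than an error.

The interaction test statistic is the pseudo-F
(SS_int/df_int)/(SS_res/df_res). Its null distribution comes from RRPP:
residuals of the reduced additive model are permuted whole across
observations and added back to the reduced fitted values, and the full model
is refit. Because the reduced fitted values lie inside the full model's
column space, both SS terms of the refit depend only on the permuted
residual matrix, which is what the implementation computes (two fixed
projection matrices applied per permutation). The observed F is therefore
exactly permutation-free, and is verified in tests against the classical
two-way ANOVA F on univariate data.

p-values count the observed arrangement: p = (b + 1)/(m + 1), so p ≥
1/(m+1) and the test is exact-valid at any m. The effect size Z is the
plain standard deviate of the observed statistic against the permutation
distribution (observed value included); a log transform of positive
statistics before standardisation is available as an option, since published
permutation frameworks differ on this point and the two Z scales are not
directly comparable. Default m = 999 for all trajectory tests (resolution
0.001, the floor at which strong effects saturate); the parallelism module
defaults to m = 10,000.

Exchangeability caveat: RRPP assumes residuals are exchangeable across
observations. If observations share a replicate-level random effect (the
same populations measured at every transfer), that effect inflates the
residual sum of squares but cannot enter the interaction subspace, making
the test conservative — in simulations with replicate-effect sd half the
residual sd, type-I error at α = 0.05 drops to below 0.01, versus ≈ 0.04–0.05
under exchangeable residuals (the calibration tests in
`tests/test_acceptance.py` simulate the latter). Users with strong
replicate effects should regard interaction p-values as conservative, or
remove replicate means first.

## Trajectory geometry

Path length is the summed Euclidean distance over consecutive least-squares
means. Direction is the first eigenvector of the covariance of a
trajectory's points; its sign is oriented so the start-to-end displacement
projects positively, falling back to the first non-degenerate consecutive
displacement, and raising a degenerate-direction error rather than guessing
when every projection is numerically zero (e.g. a perfectly symmetric
out-and-back path). Angles use |cos| and so live in [0°, 90°]. Shape
configurations are centred, scaled to unit centroid size, and superimposed
by orthogonal Procrustes rotation (reflections allowed); the shape distance
is the Frobenius norm of the aligned difference. Pairwise treatment
comparisons of all three attributes recompute the attribute on every RRPP
pseudo-dataset (reduced model: treatment + time).

Substrates are analysed on their raw respiration scale by default, matching
a covariance-based PCA of fitted values; `scale=True` standardises columns
first. The ancestral (transfer 0) phenotype is included as a shared first
trajectory point whenever the input table contains transfer 0, as the
generator's tables do.

## Parallelism statistics

The Jaccard similarity matrix is computed over all ordered clone pairs after
restricting each clone's mutations to a class filter (default:
nonsynonymous, since parallelism claims concern loci under selection;
`class_filter=None` uses all classes). Two mutation-free clones score 1 by
default (identical, empty profiles); the convention is configurable to 0
because the source literature does not state one, and the choice materially
affects matrices with many zero-mutation clones.

The permutational ANOVA treats all N² ordered cells, diagonal included, as
observations grouped by unordered treatment pair — the grouping that yields
denominator df N² − T(T+1)/2 (570 for 24 clones and 3 treatments). Cells
from one matrix are strongly dependent (the diagonal is constant at 1;
rows share a clone), so the default permutation unit is the clone→treatment
label map, which preserves the dependence structure; permuting cell values
over groups is available for sensitivity analysis but is badly
anticonservative under the null (measured rejection ≈ 0.9 at α = 0.05 in
simulations) and should not be used for inference. Pairwise contrasts
compare between-treatment cells against the pooled within-treatment cells of
the two treatments with a pooled-variance t (negative t = between-treatment
similarity below within-treatment similarity, i.e. genetic differentiation),
with two-sided permutation p-values under the same scheme.

Known limitation: the clone-label permutation null has a heavy right tail
when the parallelism signal is carried by a minority of clones. With 24
clones averaging 1.375 mutations (so ~25% mutation-free) and a single
treatment-exclusive hotspot locus drawing half of each clone's mutations,
the test's power at α = 0.05 is only ≈ 0.2 (computed in
`tests/test_acceptance.py`, which asserts the > 0.8 design goal and fails
honestly): random label assignments frequently concentrate hotspot carriers
or zero-mutation clones enough to produce permuted F values of the observed
magnitude. Power rises with carriage (≈ 0.9 when the hotspot draws 70% of
mutations), with the empty-union-0 convention, and with larger locus pools,
but the calibrated scheme is intrinsically less powerful than the
anticonservative cell-value scheme at this design size. Welch's ANOVA on
mutation counts is implemented in closed form (Welch–Satterthwaite
denominator df) and cross-checked against an independent implementation in
the tests.

## Community statistics

Bray–Curtis dissimilarity follows its defining formula on nonnegative
profiles and is applied to all unordered replicate pairs at each transfer,
for species profiles and for 7-substrate phenotype profiles alike (raw
respiration values, consistent with the trajectory analysis). The
phenotype–community covariance model regresses phenotype dissimilarity on
community dissimilarity, transfer as a continuous covariate, and their
product; the reported F is the partial (squared-t) F of the interaction with
1 numerator df. Observations are replicate pairs × transfers with no
correction for the non-independence of pairs sharing a replicate — this
mirrors the field's common practice for this design and will somewhat
overstate effective sample size; treat the interaction p as descriptive.

## Growth statistics

The Malthusian parameter defaults to the whole growth cycle (ln-fold change
over the assay; 6 days in the emulated design) rather than per day — the
scale factor is common to all observations and cancels from every F
statistic, which a test verifies. The two-way ANOVA uses Type-I sums of
squares (orders coincide on the balanced designs the generator produces);
Tukey HSD uses the studentized-range distribution with pooled within-group
variance.

## The synthetic-data generator

The generator emulates a 3-treatment serial-transfer design: a focal
degrader evolving in monoculture (MC), with a community reset to ancestral
composition each transfer (RP), or in a freely co-evolving dynamic
polyculture (DP); transfers 0/4/8/12/16; 7 lignocellulose substrates (4
labile, 3 recalcitrant); 6 replicates per treatment.

Defaults and why:

- **Phenotypes.** value = baseline 1.0 + per-treatment cumulative
  displacement + replicate effect N(0, 0.05) + residual N(0, 0.1),
  truncated at the assay floor of 0. Gaussian noise is a stand-in — the
  respiration assay's error distribution is not characterised — and the
  replicate effect is a single scalar shared across substrates, mimicking
  population-level growth differences. Default displacements encode the
  design the analysis is meant to detect: MC drifts a short distance, RP
  moves steadily along the labile substrates (~0.25 units/transfer ≈ 2.5
  residual sd), DP follows the labile direction then turns to the
  recalcitrant substrates mid-series, producing the path-length, direction
  and shape contrasts the trajectory statistics measure.
- **Mutations.** Counts per clone are Poisson(λ = 1.375), the 33-mutations/
  24-clones rate of the emulated study; 66.6% of mutations are
  nonsynonymous. Loci are drawn without replacement from an abstract pool of
  50 labels — small enough that parallel hits occur at realistic rates —
  with per-treatment multinomial weights; the default weights put a shared
  hotspot (locus L00, playing the role of a parallel-evolving regulator) at
  weight 0.5 in DP and 0.33 in MC, uniform in RP.
- **Community.** Species log-abundances per replicate take i.i.d. N(0, 0.4)
  steps per transfer and are softmax-normalised — phenomenological species
  sorting with exact compositional closure, no mechanistic resource
  dynamics. The reinvasion scenario forces one designated species to
  near-zero over the middle transfers, then releases it, in ⌈n/2⌉
  replicates (3 of 6 by default).
- **Growth.** End density = 1e6 × exp(m + N(0, 0.2)) over a 6-day cycle,
  with m = ln 100 alone for every genotype, +0.8 in community, and +1.6 for
  RP in community — a pure treatment × condition interaction of the kind
  the two-way ANOVA targets.

Each generator draws from `default_rng(seed + k)` with a fixed offset k per
generator, so adding one output to a pipeline never perturbs another's
draws, and equal seeds give byte-identical tables.

What passing tests on these data do **not** show: the generators draw
phenotype, mutation, community and growth tables independently, so
cross-layer couplings present in real data (e.g. a species' abundance
driving a substrate phenotype, or hotspot mutations causing the recalcitrant
shift) are absent; the endpoint abundance–phenotype regression on default
synthetic data is therefore null. Real respiration error need not be
Gaussian or homoscedastic; real communities are not softmax random walks.
The suite demonstrates correctness and calibration of the statistics, not
biological realism of the generator.

## Problem sizes used in the automated checks

Calibration tests use 500 simulated datasets with 199 permutations each;
power and recovery tests use 200 simulations; complete-enumeration checks
use the smallest replicated factorial (8 observations, 8!−1 permutations)
and 4-clone label enumerations. These sizes put Monte-Carlo error well
inside the asserted tolerances (e.g. se ≈ 0.01 for a rejection rate near
0.05 at 500 simulations) while keeping the whole suite fast.
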