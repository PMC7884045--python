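# Methods

`twinewas` implements an epigenome-wide association workflow for twin
cohorts that pairs an assumption-free dependence measure with twin-aware
linear mixed models, combines them per CpG, and extends single-site
results to differentially methylated regions (DMRs).  A synthetic twin
methylome generator with ground-truth labels makes every stage testable
without access-restricted individual-level data.  This note records the
models, the numerical choices, and what the synthetic experiments do and
do not establish.

## The association score (GCC)

For a methylation vector x and phenotype y (both covariate-adjusted), the
generalized correlation coefficient is a likelihood-ratio dependence
measure

    A = max(0, 1 - exp(-(2/n) (ll_joint - ll_indep)))

where `ll_joint` is the leave-one-out (LOO) log-likelihood of a Gaussian
product-kernel density over (x, y), maximized over a bandwidth grid, and
`ll_indep` is the analogous maximized product-of-marginals likelihood.
Both margins are first rank-transformed to normal scores, so A is
invariant under strictly monotone transformations of either variable and
no marginal shape can masquerade as signal.  `(ll_joint - ll_indep)/n`
estimates the mutual information I(x, y); in the bivariate Gaussian limit
A therefore converges to `1 - exp(-2I) = rho^2`, which makes the score
read like a familiar R^2 (verified at n = 2000: A = 0.80 at rho = 0.9).
A = 0 denotes independence; A -> 1 a deterministic relationship of any
shape.

Numerical choices:

* **Bandwidth grid.** 8 log-spaced values spanning [0.1, 1.5] x
  Silverman's rule (1.06 sigma n^(-1/5)) on the normal-score scale.  One
  shared bandwidth is applied to both axes of the joint kernel: after
  rank standardization the two margins are the *same* score set, so there
  is no scale asymmetry for an anisotropic bandwidth to absorb, and the
  diagonal grid preserves the Gaussian-limit identity at an eighth of the
  cost.  The LOO likelihood removes the degenerate zero-bandwidth
  maximum.
* **Kernel truncation and flooring.** Kernels are truncated at +-6
  bandwidths (relative error < 1e-8) and LOO densities floored at 1e-35
  (float32 underflow guard).  Both conventions apply identically to
  observed and permuted evaluations, so permutation tests remain exact.
* **Rank-statistic caching.** For tie-free data the normal-score vectors
  of x and y are the same fixed set of n values; the statistic depends on
  the data only through the permutation matching x-ranks to y-ranks.
  Kernel matrices over the score set are therefore cached per sample
  size, and one evaluation is a banded gather-and-sum over that matching
  permutation (a compiled kernel; ~1 ms at n = 400).  Tied data fall back
  to a general two-margin evaluation.

**Significance.**  `gcc_pvalue` permutes y: p = (1 + #{permuted stat >=
observed}) / (n_perm + 1).  Ranking uses the unclipped likelihood-ratio
statistic; ranking by the clipped score would place half the null mass in
a tie atom at zero and destroy p-value uniformity.  With `tail="gpd"` and
fewer than 10 exceedances, a generalized-Pareto tail fitted to the top
10% of the permutation distribution extrapolates below the empirical
floor 1/n_perm; fit failures fall back to the empirical p with a flag.
Because the null distribution of the rank statistic depends only on n,
genome-wide scans and power studies may instead rank each probe against a
precomputed null reference table (default 19,999 draws, seeded), which
resolves p-values far below a per-probe permutation budget; the
calibration harness always runs honest per-replicate permutations.

**Scope of validity.**  Sample-level permutation assumes exchangeable
samples.  The twin phenotype is pair-correlated, which alone does not
break the test (the marker is permuted); but when the *marker* is also
strongly pair-correlated the effective sample size shrinks and the test
inflates mildly (measured: lambda ~ 1.10-1.15 when every probe shares 20%+
of its variance within pairs).  The study this emulates observed no such
inflation on real twin methylomes (lambda = 0.99), consistent with the
known right-skewed distribution of CpG twin-correlations in adjusted
blood methylomes - most probes carry little familial variance.  The
generator reproduces that regime (below).

## Twin-aware linear models

Two mixed models handle the within-pair correlation:

* **Pair random intercept (LME):** y = b0 + b1 x + b_pair + e with
  b_pair ~ N(0, sigma2_b).
* **Kinship covariance:** y = Xb + g + e with cov(g) = sigma2_g R, where
  R = 2 Phi is the relationship matrix (1 for MZ co-twins, 0.5 for DZ, 1
  on the diagonal).

Both are the same model family: the pair random intercept is the kinship
model with a block-of-ones R, so one profiled-ML engine serves both (and
for MZ-only cohorts they agree to numerical precision, a tested
invariant).  Fitting rotates y and X by the eigenvectors of R (computed
once per cohort and reused across all CpGs), profiles the variance ratio
sigma2_g/sigma2_e on a log grid (161 points over [1e-4, 1e4] plus 0,
bounded scalar refinement for single fits), and reports a two-sided Wald
test of the methylation coefficient.  ML rather than REML keeps per-CpG
likelihoods comparable and the rotation exact; the grid-only vectorized
scan and the refined single-probe fit agree to ~1e-3 in p.  The ratio
grid includes 0, so boundary estimates degrade gracefully to OLS.
Orientation: the phenotype is the outcome and methylation the predictor
(matching the covariate-screen model and printed coefficient magnitudes
of the study design); a transposed orientation can be fitted by passing
arguments swapped, since the engine is agnostic to the labels.

Verification: dense-GLS closed form at a pinned variance ratio,
brute-force 2-D likelihood grid on a 3-pair fixture, parameter recovery
at 200 pairs, and agreement with an independent mixed-model
implementation (statsmodels MixedLM, ML) on coefficient (1e-4) and
standard error (5%, the two use slightly different information
matrices).  Type-I error on null markers against the twin-correlated
phenotype: 0.051-0.054 at alpha = 0.05 (10,000 replicates), mirroring
the mild anticonservatism the reference analysis reported (0.054/0.055).

## The combined scan

`run_ewas` residualizes the phenotype and every probe (OLS on intercept +
age + sex + five leukocyte fractions) so all three models see identical
adjusted data - the GCC has no covariate slot, and pre-residualization
keeps the comparison fair.  Per probe it reports the A score, GCC
p-value, kinship coefficient and p, LME p, the combined
p = min(p_gcc, p_kin) with a provenance flag, BH-FDR q-values, and the
effect direction from the sign of the linear coefficient (the score
itself is directionless; a nonlinear relationship has no sign).  The LME
is reported but excluded from the combination by default (the kinship
model is the linear representative; config-switchable).  The minimum of
two p-values is deliberately *not* null-corrected - the reference
workflow applies BH directly to the min-p values - so under independence
P(p_combined < a) = 1 - (1-a)^2, an inherited selection inflation that is
asserted, not hidden.  Summaries: genomic inflation factor per model
(lambda = median chi-square / 0.4549), counts at p < 1e-4/1e-5/1e-6, a QQ
table, and the count of probes passing the loosest threshold in both
models.

## Region calling

The DMR stage re-implements the comb-p procedure on the combined
p-values:

1. **ACF estimation**: correlation of z = Phi^-1(1-p) over probe pairs,
   binned by distance (default edges 1, 50, ..., 500 bp; >= 30 pairs per
   bin or the bin reports 0 with a flag; rho clipped to [0, 1]).
2. **Stouffer-Liptak smoothing**: each probe's p is replaced by the
   combination of all probes within +-window/2 (default 1 kb), with
   pairwise sigma filled from the ACF; z_c = sum(z)/sqrt(1' sigma 1).
   Non-PSD empirical sigma is repaired by eigenvalue clipping.
3. **Peak finding**: seed below 1e-3, extend at the same threshold across
   gaps <= 500 bp, require >= 2 probes.
4. **Region scoring**: Stouffer-Liptak over the members' *original*
   p-values; Sidak correction 1 - (1 - p)^(covered bases / region span)
   computed via expm1/log1p so tiny p survive; BH q-values across
   candidate regions (the headline column); hyper/hypo direction from the
   mean sign of member coefficients.

The parameters mirror the cited algorithm's common defaults and are
config-exposed.  A known behavior inherited from the algorithm: an
extreme isolated single-CpG p-value drags its neighbours' smoothed
p-values down and can spawn a 2-probe region around itself, so region
calls near strong single-site hits deserve inspection; the null
false-positive rate of the full pipeline is clean (no q < 0.05 regions in
8/8 null scans, shuffled or not).

## Synthetic cohort and methylome

The generator's defaults emulate the discovery-cohort profile:

* **Cohort** (`CohortConfig`): 200 MZ pairs; co-twins share age and sex;
  age from a truncated normal on [56, 80] *moment-matched* so the realized
  sample mean/sd equal 66.55/5.96 (the printed statistics describe the
  bounded sample; naive truncation of N(66.55, 5.96^2) would shift the
  mean to ~66.9); 45% female; the cognitive composite is the standardized
  sum of five standardized subscores, each mixing a shared pair component
  (variance 0.5 by default - the study shows pairwise concordance but
  prints no ICC) with individual noise plus age and sex effects.  The
  effect defaults (-0.02/yr, +0.15 F-M per subscore) were set so the
  covariate screen reproduces the study's printed associations (age z ~
  -4.3, sex z ~ +3.0 at n = 400); the resulting within-pair score
  correlation is ~0.55.  Cell fractions are Dirichlet draws around
  typical leukocyte proportions, scaled to sum slightly below 1
  (unclassified cells exist; this also keeps the covariate design
  full-rank).
* **Methylome** (`MethylomeConfig`): one synthetic chromosome; gaps from
  a mixture of island-like (~50 bp) and open-sea (~5 kb) spacings;
  bimodal beta baseline (modes 0.15/0.85); all noise, sharing and effects
  act on the M scale and map back through the inverse logit so betas stay
  strictly in (0, 1).  Spatial correlation is a first-order
  autoregression along position with decay exp(-gap/200 bp).  Twin
  sharing is per-probe Beta(0.5, .)-distributed with mean 0.10 (DZ share
  halved): the right-skewed law matches adjusted blood methylomes, where
  the median CpG carries little familial variance, and was calibrated so
  the full-null scan reproduces the study's printed inflation factors
  (measured over seeds: GCC 1.02 +- 0.05, kinship 1.04 +- 0.05, against
  printed 0.99/0.95/0.94).  A constant high share would instead inflate
  the GCC scan (lambda 1.1+), contradicting the study's observed
  behavior.
* **Effects**: single-CpG implants by shape (linear, quadratic, sine,
  step, variance - all standardized to unit variance, the nonlinear ones
  orthogonal to the linear trend), effect size in M-value units per sd of
  the shape (default 0.25, i.e. half the default noise sd - a strong,
  clearly recoverable effect appropriate for truth-recovery testing);
  region implants are runs of 5 consecutive probes within 1 kb sharing a
  signed linear effect.  Sex-chromosome / SNP / cross-reactive flags are
  injected without signal, only to exercise the filters.

What the generator does *not* emulate: array normalization artifacts and
batch effects, realistic cell-type deconvolution mixtures, genotype-
driven methylation (flagged probes are stand-ins), chromosome-specific
structure, and the long-range correlation of real epigenomes.  Passing
tests therefore establish that the statistics behave as designed under
the modelled structure (twin pairing, spatial decay, bimodality,
nonlinear effects), not that the pipeline is robust to every artifact of
real arrays.

## Calibration, power, replication

`type1_error` draws a single marker i.i.d. N(0,1) per replicate,
independent of the (covariate-adjusted) phenotype, and records the
rejection fraction +- Monte-Carlo se.  The GCC path runs an honest
999-permutation test per replicate; evaluation stops once enough
exceedances have accrued that p < alpha is impossible, which leaves the
decision identical to the full run.  The linear models are calibrated
with the vectorized scan (10,000 replicates in seconds).  `power_curve`
implants shaped effects at a grid of sizes; the GCC side uses the null
reference table so alpha = 1e-3 is resolvable with 200 replicates.
Measured at n = 400: sine/quadratic power ~1.0 for GCC vs ~alpha for the
linear models; pure linear effects favour the linear models - the two
families capture disjoint top lists by design.

`binomial_replication_p` and `hypergeom_overlap` compute exact upper
tails by direct summation in rational arithmetic (Fraction/integer), with
recursive-ratio and exhaustive-enumeration oracles in the tests.  Note
P(X >= 9; 65, 0.05) = 4.93e-3 exactly.

## Problem sizes and determinism

Every stochastic routine takes a seed and is bitwise reproducible.  The
shipped experiments use: 2,000-probe methylomes; 2,000 replicates for the
GCC calibration (999 permutations each) and 10,000 for the linear models;
200 replicates for power; 50 seeds for the DMR recovery study.  These
sizes put Monte-Carlo error well inside the tolerance of every asserted
band while keeping a full run on one core in the tens of minutes.

## Known limitations

* Sample-level permutation for the GCC mildly inflates when a marker is
  strongly pair-correlated (see above); a pair-exchangeable permutation
  scheme would remove this at ~n_perm-fold per-probe cost and is not
  implemented.
* The min-p combination is reported uncorrected, faithful to the
  reference workflow; its selection inflation is documented and tested.
* The Wald tests use ML variance estimates; at n = 400 this contributes
  the familiar ~0.003 anticonservatism visible in the calibration.
* GPD tail fitting requires >= 30 exceedances over the 90th percentile
  and falls back (flagged) otherwise.
* `bh_fdr` with an external m_total can only reproduce published FDR
  values whose step-up minimum falls inside the supplied list; values
  driven by unprinted p-values are bounded, not matched.
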