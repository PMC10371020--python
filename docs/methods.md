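# Methods

This note documents the statistical models, default parameters, and
numerical conventions implemented in `rloopscape`, and what the
synthetic-data generator does and does not emulate.

## Enrichment model

Counts are binned (default 100 bp, chosen so that analyses of the first
100 bp of coding sequences are resolved at native resolution) and
organised per genotype into unstranded *input* libraries and
strand-resolved *extracted* (pull-down) libraries. For one genotype and
strand, bin *i* and library *l* follow

    y_il ~ NegBin(mu_il, phi),  log mu_il = log s_l + alpha_i + ln2 * beta_i * e_l

with `e_l = 1` for extracted libraries. `beta_i` is the log2 enrichment.
Replicates are independent draws from the shared `beta_i` (no replicate
random effect). Input libraries enter both strand models, so the two
strands share their abundance information but have independent
enrichments.

*Priors.* `alpha ~ Normal(log(mean normalised depth), 3^2)`,
`beta ~ Normal(0, 2^2)` on the log2 scale. These are weak at the default
depth; they matter only for nearly empty bins.

*Dispersion.* One `phi` per genotype (variance `mu + mu^2/phi`),
estimated by a Pearson moment equation with a degrees-of-freedom
correction: solve `sum (y - mu)^2 / (mu + mu^2/phi) = n_bins *
(n_libraries - 2)` given the per-bin MAP means, iterating estimate and
refit twice. Per-bin parameters absorb part of the replicate
variability, which is why the naive profile MLE diverges; the moment
equation with the 2-parameter correction is stable. Sub-Poisson
residuals return an effectively infinite `phi` (Poisson limit).

*Engines.* The default `vi` engine computes, per bin, the MAP by Fisher
scoring and a Gaussian approximate posterior from the expected
information plus prior precision (bins are conditionally independent
given `phi`, so this is a mean-field approximation across the genome);
500 draws of `beta` are sampled from it. The `mcmc` engine runs a
vectorised random-walk Metropolis on `(alpha_i, beta_i)` for all bins in
parallel, preconditioned by the Laplace covariance (2500 steps, 500
burn-in, thinned to the requested draws). Both are deterministic given
the seed. On the default synthetic conditions the two engines agree to
within ~0.05 log2 units per bin, and two independently seeded MCMC fits
correlate at r > 0.99.

*Spike-in normalisation.* Size factor of library *l* is its summed count
over spike-in bins divided by the geometric mean of those sums across
libraries. The spike-in is modelled as a separate contig with a constant
true enrichment — an unchanging reference. With the default reference
level of 0 the spike contributes identically to input and pull-down
fractions and genome scores are absolute; any other constant merely
shifts all scores to be relative to the spike reference (the log base
and engine are recorded in the run manifest).

*Masking.* Bins overlapping masked intervals (e.g. duplicate rRNA
copies, mirroring analysis against a single rRNA consensus) are excluded
from the fit and emitted as flagged null records, never silently
dropped.

*Contrasts.* Genotype contrasts subtract posterior draws paired by draw
index on identical bins, then convert the per-bin means to robust
z-scores and smooth with a 500-bp rolling median.

## Track operations

- **Robust z**: `(x - median) / (1.4826 * MAD)`. A zero MAD raises a
  `ScaleError`; callers may opt into an IQR/1.349 fallback. Missing
  values stay missing.
- **Rolling median**: centered window of `ceil(window/bin)` bins, forced
  odd; edge windows truncate rather than pad, keeping genome-length
  tracks aligned (circular wrap-around is deliberately not applied, to
  match linear plotting). NaNs are excluded per window.
- **Coverage**: log2 CPM with a +0.5 read pseudocount recorded in the
  track metadata.
- **Replication slope z**: the log2 CPM track is smoothed with a 10-kb
  rolling median, a least-squares slope is taken over a centered 10-kb
  window (Savitzky-Golay, polynomial order 1, first derivative) on 1-kb
  bins, signed along the direction of fork travel on each replichore so
  fork slow-down is strongly negative, and converted to robust z. A
  slope constant up to float jitter short-circuits to all-zero z with a
  `degenerate_scale` flag. The 10-kb slope window is a parameter; the
  default matches the smoothing scale used for terminus-region coverage
  profiles.
- **Event density**: Gaussian kernel density on a 512-point grid with
  the classical rule-of-thumb bandwidth
  `adjust * 0.9 * min(sd, IQR/1.34) * n^(-1/5)`; transversion-density
  plots use `adjust = 0.2`. The grid spans the data ± 3 bandwidths
  (clipped to the genome), over which the density integrates to 1 within
  1%.

## Replichore geometry

Replication initiates bidirectionally at `oriC_pos` and terminates at
`ter_pos`; on the arc from oriC to ter in increasing-coordinate
direction forks travel `+`, on the other arc `-`. A gene is
*codirectional* when transcribed with fork travel, *head-on* otherwise.
Genes spanning oriC or ter are classified by the arc containing their
midpoint and flagged (`boundary_flag`) — the source analyses do not
state a rule for this rare case, so the midpoint convention is this
package's documented choice. The terminus position is required
configuration, never inferred from coverage. Orientation calls are
invariant under genome rotations that preserve the oriC/ter geometry.

## Feature statistics

Feature scores are medians of same-strand robust-z bins whose midpoints
fall inside the feature (or its strand-aware first 100 bp); features
with no usable bin propagate as missing. Expression z is the robust z of
log2(CPM + 0.5), computed once per genotype; "top 20% expression"
filters threshold the expression z per genotype with ties kept above the
threshold. Unpaired comparisons use the Wilcoxon rank-sum test (exact
for groups of at most 25 without ties, normal approximation with
continuity correction otherwise) with the Hodges–Lehmann median
difference; cross-genotype comparisons are paired by feature and use the
signed-rank test on per-feature differences. All CIs are percentile
bootstrap (default 10^4 resamples, seeded); the CI construction used in
the source figures is not stated, so bootstrap is this package's
documented choice. p-values are Benjamini–Hochberg adjusted across the
battery actually run.

The orientation regression is a Gaussian Bayesian linear model
`z ~ 1 + head_on + expr_z + head_on:expr_z` with `Normal(0, 2^2)`
coefficient priors and a half-Normal(0, 2^2) residual scale.

## Mutation-accumulation analysis

Event tables use 1-based inclusive coordinates. Substitutions are
classified transition/transversion from ref/alt (strand-symmetric);
indels by length difference. Structural variants within 100 bp of a
line's engineered alteration are removed — the exclusion window has
*inclusive* endpoints (`[start-100, end+100]`), and an SV touching the
boundary is removed. Lines whose SVs hit a guarded gene (e.g. a
mismatch-repair locus, whose loss would corrupt the mutation spectrum)
are excluded with a report.

Rates are `events / exposure` with exact Garwood bounds
(`Gamma(k).ppf(0.025)/E`, `Gamma(k+1).ppf(0.975)/E`; lower bound 0 at
zero events). Rate comparisons condition on the total count: under rate
equality `X1 ~ Binomial(n, t1/(t1+t2))`, giving the exact one- or
two-tailed rate-ratio test.

The rate regression models per-CDS counts per class as
`count ~ Poisson(exposure * exp(X beta))` with exposure = CDS length
(bp) × summed generations, `Normal(0, 2^2)` coefficient priors, and
standardized continuous covariates. Exposure uses full CDS length for
every class; per-class available-site subsetting is deliberately off.
The three classes are fit independently (no parameters are shared across
classes, so the joint model factorises). The Poisson likelihood is the
default for these small counts; the design matrix (genotype dummies,
hybrid z, expression z, head-on, and head-on interactions) is
configurable rather than hard-coded.

*Sampling.* An affine-invariant ensemble sampler with `max(4*ndim, 32)`
walkers, vectorised log-probability, walkers initialised in a tight ball
around the MAP. Ensemble autocorrelation times for these GLM posteriors
run ~10× the dimension, so the sampler budgets 15 autocorrelation
lengths of burn-in and 50 of sampling, thinning the kept chain to the
requested draw count; convergence is diagnosed by rank-normalised split
R-hat on a moderately thinned post-burn chain, with an error above 1.05.
Against closed-form references the posteriors match OLS/GLM point
estimates and standard errors.

*Bayes factors.* With ROPE half-width `delta` (default 0.05 on the
log-rate scale, ~5% rate change; echoed in every output) and the
dominant posterior sign `s`:

    K  = [P(s*beta > delta | data) / P(|beta| <= delta | data)] / [prior odds]
    K0 = [P(|beta| <= delta | data) / P(|beta| > delta | data)] / [prior odds]

with prior cell masses computed analytically from the Normal prior.
Posterior cells are estimated from draws; empty cells are clamped to
`1/n_draws` with a warning, so K is capped at finite draw counts.
Categories: K in [3,20) positive, [20,150) strong, >= 150 very strong
(same bins for K0).

*LOO.* Pointwise log-likelihoods are stored per draw and fed to
PSIS-LOO; comparisons report the ELPD difference and the SE of the
pointwise differences, counting observations with Pareto k > 0.7. For
nested models differing by a null covariate the ELPD difference
concentrates near half an overfit parameter while the paired SE becomes
unreliable — the standard guidance is that differences below ~4 ELPD
units are negligible regardless of SE — so `LooComparison.
indistinguishable` applies `|diff| < max(2*SE, 4)`. Discriminating
comparisons (planted-effect covariates) produce differences orders of
magnitude above this threshold.

## Synthetic-data generator

The generator emulates, with planted ground truth written alongside
every output:

- a circular 200-kb genome (oriC at 0, ter at 100 kb) with
  non-overlapping CDSs (each with a 5'-UTR, half with a 3'-UTR), ncRNAs,
  tRNAs, one rRNA consensus plus masked duplicate copies; genes are
  head-on with probability 0.25, the codirectional bias real bacterial
  genomes show;
- per-gene log2 expression ~ Normal(5, 2) with its robust z;
- planted per-bin log2 enrichment: feature-type effects (5'-UTRs and
  rRNA highest), a per-genotype expression slope (strongest in the
  R-loop-nuclease deletion), a small positive head-on effect and a
  negative head-on × expression interaction, plus a differential region
  for genotype-contrast tests — the qualitative structure the pipeline
  is meant to resolve;
- negative-binomial input counts at 100 reads/bin and extracted counts
  at `input mean x 2^beta x size factor`, dispersion phi = 1000
  (variance 10% above Poisson at the default depth, representative of
  high-quality bacterial sequencing bins; a Poisson switch exists), with
  lognormal library size factors (sd 0.15) and a spike-in contig for
  normalisation. Two replicates per library class. At these conditions
  the per-bin posterior SE is ~0.15 log2 units, which is what the
  ±0.25-recovery checks presume;
- replication WGS coverage on 1-kb bins, piecewise-linear in log2 space
  from oriC to ter (1 log2 unit total drop), with planted
  slow-replication intervals where the slope steepens 4×, persisting
  downstream on the same replichore — the slope-as-proxy logic the
  replication profiling uses;
- MA lines (72 per genotype, 3700 generations each) with per-CDS Poisson
  mutation counts from planted log-linear coefficients (baseline
  3.5e-10 /bp/generation, a realistic bacterial MA-line scale),
  uniformly placed events with class-consistent ref/alt alleles,
  structural variants at planted per-genotype rates (wild-type
  2.2e-5/generation, elevated in the R-loop-nuclease deletion),
  breakpoint artefacts near each line's engineered locus to exercise the
  SV filter, and a guarded mismatch-repair-like locus.

For regression calibration studies a direct table generator bypasses the
genome: standard-normal covariates (optionally correlated), Bernoulli
orientation labels, and a common exposure scaled so the baseline
expected count per CDS is 2 — enough signal that a planted coefficient
of 0.5 is estimated with SE ~0.02. The LOO discrimination study uses
n = 1500 CDSs because the pointwise ELPD-difference signal-to-noise
under a planted unit effect is ~0.14 per observation, so the 4-SE margin
needs n ≳ 830. The correlated-covariate robustness study plants both
effects at 0.1: omitted-variable bias makes the leave-one-out shift
approximately `rho × beta_other`, so the observed stability of real
inferences is itself evidence that the real associations are of this
subtle scale, and the study conditions reflect that.

What the generator does **not** emulate: raw reads (counts are drawn
directly, so mappability, GC and fragmentation biases are absent),
sequence-dependent mutation hotspots, selection within MA lines, operon
structure, and copy-number variation along the replication gradient in
the pull-down input (the oriC-ter gradient is optional there and flat by
default, since the measurement model — not replication skew — is what
the enrichment tests exercise). Passing recovery tests therefore
demonstrates correctness of the inference given the stated measurement
model, not robustness to alignment-level artefacts.

## Reproducibility

Every stochastic component takes an explicit seed; a fixed seed
reproduces simulator output byte-for-byte and identical posterior draws
across processes. The pipeline manifest records the config hash, seeds,
version, per-file SHA-256 digests, and stage timings; re-running with
the same config and seed reproduces the digests.

## Limitations

- The Gaussian approximate posterior is per-bin; it does not propagate
  uncertainty in the shared dispersion or size factors (both are
  precisely estimated at the default depth, but at very low coverage the
  intervals will be mildly optimistic).
- Bayes factors are draw-based and clamped at `1/n_draws`; values at the
  clamp ceiling should be read as "at least this large".
- The exact Wilcoxon path requires tie-free data; ties fall back to the
  normal approximation with continuity correction regardless of group
  size.
- The conditional rate-ratio test and Garwood intervals are exact but
  conservative for very small exposures.
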