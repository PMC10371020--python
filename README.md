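# rloopscape

Genome-wide analysis of RNA:DNA hybrid (RDH) accumulation and its
mutagenic consequences in bacteria, built for strand-specific
hybrid-binding-domain (HBD) pull-down sequencing, replication profiling
from binned whole-genome coverage, and mutation-accumulation (MA) line
data.

RNA:DNA hybrids — R loops, Okazaki-fragment primers, misincorporated
ribonucleotides — are removed by RNase H enzymes; when removal fails they
stall replication forks and mutate the genome. Dissecting *where* hybrids
accumulate and *what* they do to mutation rates requires (i) calibrated
per-bin enrichment inference from noisy pull-down vs input sequencing,
(ii) careful accounting for the confounders of hybrid biology — gene
expression level and the head-on/codirectional orientation of a gene
relative to replication-fork travel — and (iii) rate statistics for the
sparse mutation counts MA lines produce. `rloopscape` implements that
whole computational path as a reusable library plus a `rloopscape` CLI,
and ships a synthetic-data generator that plants known ground truth for
every stage, so each statistical claim the pipeline can make is backed by
a recovery or calibration test.

## Models at the core

**Per-bin enrichment.** For each genotype and strand, bin *i* with
abundance α\_i and log2 enrichment β\_i generates library counts

    y_il ~ NegBin(mu_il, phi),   log mu_il = log s_l + alpha_i + ln(2) * beta_i * e_l

where s\_l is a spike-in-derived size factor and e\_l flags the extracted
(pull-down) library. Input libraries are unstranded and shared by both
strand models; the dispersion φ is per-genotype (variance μ + μ²/φ).
Priors: α ~ N(log depth, 3²), β ~ N(0, 2²). The default engine draws 500
posterior samples per bin from a Gaussian (Laplace) approximate
posterior; a vectorised Metropolis engine is available for exact
small-genome runs. Enrichment tracks are summarised as robust z-scores
(x − median)/(1.4826·MAD), smoothed by rolling medians, and contrasted
between genotypes by paired posterior draws.

**Feature statistics.** Per-feature scores are the median robust z over
same-strand bins (bin counted if its midpoint falls inside; masked rRNA
copies excluded). Head-on vs codirectional and cross-genotype paired
comparisons use Wilcoxon tests with Hodges–Lehmann estimates, percentile
bootstrap CIs, and Benjamini–Hochberg FDR (stars: \* 0.01≤FDR<0.05,
\*\* 0.001≤FDR<0.01, \*\*\* FDR<0.001), plus a Bayesian regression of CDS
hybrid z on orientation × expression.

**Mutation rates.** Per-genotype rates carry exact (Garwood) Poisson 95%
CIs; genotype contrasts use the exact conditional binomial rate-ratio
test. Per-CDS counts of transitions, transversions, and indels are
modelled as exposure-offset Poisson regressions on hybrid z, expression
z, orientation, genotype, and interactions, sampled with an ensemble MCMC
sampler. Evidence per coefficient is summarised by ROPE Bayes factors:
*K* for a substantial effect and *K₀* for a near-zero effect
(K ∈ [3,20) positive, [20,150) strong, ≥150 very strong), and models are
compared by PSIS-LOO expected log predictive density.

## Worked example

```python
>>> from rloopscape.mutation import rate_with_ci, rate_ratio_test
>>> est = rate_with_ci(17, 265_500)   # 17 SVs over 265,500 generations
>>> print(f"SV rate: {est.rate:.2e} per generation "
...       f"(95% CI {est.ci_low:.2e} to {est.ci_high:.2e})")
SV rate: 6.40e-05 per generation (95% CI 3.73e-05 to 1.03e-04)
>>> round(rate_ratio_test(17, 265_500, 6, 272_727, alternative="greater"), 4)
0.0148
```

A structural-variant rate of 6.4×10⁻⁵ per generation — roughly three
times the matched wild-type rate — with a one-tailed exact rate-ratio
P = 0.015: the hybrid-removal deletion genotype rearranges its genome
significantly faster.

Enrichment recovery on a synthetic 200-kb genome (2 replicates, 100
reads/bin):

```python
>>> from rloopscape.simulate import (SimConfig, simulate_genome_annotation,
...     simulate_expression, build_ground_truth, simulate_counts)
>>> from rloopscape.counts import size_factors_from_spike
>>> from rloopscape.enrich import fit_enrichment, EnrichmentOptions
>>> cfg = SimConfig(seed=42, genotypes=("WT",), differential_regions=())
>>> features, rep, mask = simulate_genome_annotation(cfg)
>>> truth = build_ground_truth(cfg, features, simulate_expression(cfg, features))
>>> counts = simulate_counts(cfg, truth)
>>> counts.size_factors = size_factors_from_spike(counts)
>>> post = fit_enrichment(counts, "WT", "+", EnrichmentOptions(seed=7))
```

which prints, comparing posterior summaries against the planted truth:

    bins within 0.25 of truth: 93.6%;  90% interval coverage: 90.3%
    estimated NB dispersion: 1287

The posterior mean lands within a quarter of a log2 unit of the planted
enrichment for ~94% of bins, the 90% intervals are close to nominally
calibrated, and the profiled dispersion is near the generator's φ = 1000.

End-to-end demo (simulate → normalise → fit → tracks → feature stats →
MA rates → mutation model → manifest; ~1 minute):

```bash
rloopscape run --config configs/demo.yaml --seed 0 --out-dir out/demo
rloopscape report --out-dir out/demo
```

Outputs include per-genotype/strand enrichment and robust-z bedGraphs,
genotype-contrast tracks, replication slope z-score tracks, feature score
tables, the comparison battery with FDR stars, the MA rate table with
exact Poisson CIs, mutation-model coefficients with K/K₀, and a
`manifest.json` whose file digests reproduce exactly under a fixed seed.

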