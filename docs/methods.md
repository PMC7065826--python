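# Methods

This note records the statistical model, algorithms, priors, and the
package's explicit definitions. Everything here is implemented in
`src/mfqtl/` and exercised by the test suite.

## Study design being modeled

Several doubled-haploid (DH) families share one common (elite) parent; each
family is a cross of the common parent to a different donor. Genotypes are
coded by parental origin: `+1` for the common-parent allele, `-1` for the
donor allele (file code `B`/`A`), `NA` missing. DH lines are fully
homozygous, so one code per locus suffices. Phenotypes are multi-environment
plot values (cropping seasons); traits of interest include flour yield
(FlYd, higher better) and flour redness (Fla, lower better).

## Genetic maps and the interval grid

All distance↔recombination conversions use the Kosambi mapping function,
`d = 25 · ln((1+2r)/(1−2r))` cM with inverse `r = 0.5 · tanh(0.02 · d)`
(`genmap.kosambi_cM` / `inverse_kosambi`; round-trip exact to 1e-10).

The scan operates on a genome-wide grid of 1-cM intervals per chromosome
(`IntervalGrid`); the last interval of a chromosome may be narrower.

A joint multifamily map is rebuilt from a physical (Mb) marker order: for
each adjacent pair, recombinant and scored line counts are **pooled across
families** before the Kosambi conversion; unlinked pairs (pooled rf ≥ 0.5)
cap the gap at 50 cM with a warning; markers scored nowhere are dropped.

## DH interval-genotype imputation

Along a DH chromosome the coded genotype is a two-state Markov chain with
transition probability = inverse-Kosambi of the gap (no interference). For
an interval midpoint with nearest scored flanks L, R at recombination
fractions r_L, r_R, writing `t = g·(1−2r)`,

`u = (t_L + t_R) / (1 + t_L · t_R)`

is the exact conditional expectation of the code (equal to brute-force
gamete enumeration; tested). Beyond a terminal flank, `u = g·(1−2r)`; a line
with no scored marker on a chromosome gets `u = 0` there with a warning.
The hard call is `sign(u)`, an exact tie resolving to the left flank.

## Phenotype preparation

One adjusted value per line and trait: a joint additive least-squares fit
of line + environment effects (sparse LSQR, sum-to-zero environment
effects) over all plots, then per-line averaging of season-corrected
values. The joint fit is unbiased under unbalanced designs where per-season
means are not.

Realized kinship: `K = W Wᵀ / m` over ±1 codes with per-marker mean
imputation. Heritability: single-component REML (`y = 1β + g + e`,
`g ~ N(0, va·K)`) solved by eigendecomposition and a 1-D profile likelihood
over `va/ve`, with a 95% profile-likelihood interval for
`h² = va/(va+ve)`. Trait correlations are pairwise-complete Pearson with
Holm-adjusted p-values.

## The multifamily Bayesian scan

Model for line j of family i:

`y_ij = μ_i + Σ_l s_il · u_ijl · a_l + e_ij`, `e_ij ~ N(0, σ²)`

with a variable number N of QTLs, each occupying one grid interval;
`s_il ∈ {0,1}` says whether QTL l segregates in family i.

**Priors** (all exposed in `Priors`): N ~ Poisson(λ=2) truncated at 20;
`a_l ~ N(0, s_a²)` with s_a = phenotypic SD by default; `s_il ~
Bernoulli(0.5)` i.i.d.; flat prior on μ_i; scale-free `1/σ²` prior on the
residual variance. QTL positions are uniform over unoccupied intervals.

**Sampler**: Gibbs updates for μ_i, a_l, each s_il and σ², plus

- reversible-jump birth/death: a birth draws an unoccupied interval, effect
  from the prior, indicators from the prior; with the prior-as-proposal the
  acceptance ratio reduces to `exp(Δloglik) · λ/(N+1) · p_d(N+1)/p_b(N)`
  (death symmetric with `N/λ`);
- position moves, 50% local (±1 or ±2 intervals within the chromosome) and
  50% genome-wide uniform, accepted by the symmetric Metropolis rule.

The sampler sees maximum-probability hard genotype calls by default
(`use_soft_u=True` switches to expectations); `fix_s=True` pins all
indicators at 1 (classic single-population Bayesian interval mapping).

**Summaries**: `p_l` = share of retained samples with a QTL in interval l;
conditional mean effect and per-family segregation frequencies are averaged
over occupied samples. **QTL intensity** of a chromosome = Σ p_l there =
expected number of QTLs on it; intensities sum to the posterior mean N
exactly (tested to 1e-10).

**Significance**: within-family permutation of adjusted phenotypes; each
permutation reruns the scan and records the maximum chromosome intensity;
the threshold is the `ceil(level·n_perm)`-th highest maximum. Permutation
chains may run shortened (¼ length by default) and the result is flagged.

**Calling**: a chromosome above the threshold yields one QTL; above twice
the threshold, two, split at the interior interval of minimal `p` whose two
sides each still exceed the threshold (the trough interval belongs to
neither region; if no valid split exists a single QTL is reported with a
warning). Reported position/effect/segregation are `p`-weighted means over
the region.

**Contribution** (this package's explicit definition of variance
explained): for a region,

`contribution = Σ_region p_l · s̄_l · a_l² · Var(u_l) / Var(y)`

where `s̄_l` is the family-size-weighted mean segregation frequency and
`Var(y)` the variance of the adjusted phenotype over all lines (which
includes genuine between-family mean differences).

## Prediction and cross-validation

From a trained field, `y_hat = μ_hat + Σ_l p_l · u_l · a_l` — every
interval contributes its posterior-mean allelic effect. The intercept is
the line's family mean when known, else the size-weighted grand mean.
k-fold CV (seed-reproducible near-equal partition; 564 lines at k=6 give
folds of 94) refits the scan on each training split and reports per-fold
Pearson correlations.

## Ideotype design

**Regions**: maximal runs of intervals with `p > 0.01`, absorbing sub-floor
gaps of length ≤ 1 flanked by qualifying runs (longer gaps separate
regions). Regions can also be taken from a curated region table annotated
with member QTLs.

**Favorable allele**: common-parent allele iff `effect × direction > 0`,
where direction is +1 for FlYd (higher better) and −1 for Fla (lower
better); in regions carrying QTLs of both traits the primary trait (FlYd)
decides.

**Ideotypes**: ideotype 1 fixes the favorable allele in every region;
ideotypes 2..n successively release the Fla-only regions in ascending order
of contribution (ties by chromosome, then position); FlYd regions stay
fixed throughout.

**Derivative genotypes**: sampled from the no-interference Markov chain
along each chromosome with transition probabilities from adjacent-interval
recombination fractions. Fixed regions are single haplotype blocks (no
internal recombination). Stretches between fixed blocks are exact Markov
bridges (backward filtering with suffix products of `θ = 1−2r`, forward
sampling), so fixed intervals match with probability 1 and no sample is
rejected; configurations that are genuinely infeasible (opposite alleles at
zero recombination) raise an error. Trait values of derivatives come from
the prediction equation, with the all-`+1` common parent as reference.

## Synthetic data generator

`SimulationConfig` defaults emulate the target study's scale: 3 families ×
188 lines, 21 wheat-like chromosomes (total ≈ 4,970 cM), ~7-cM marker
spacing, 8 planted QTLs with mixed segregation patterns (h² ≈ 0.6 at the
default residual SD), four cropping seasons with additive effects, distinct
family means, 5% missing genotypes and phenotypes. Genotypes are drawn
chromosome-wise from the DH Markov chain (Bernoulli(½) start, independent
gap recombinations); phenotypes are
`μ_family + Σ s·u·a + season + N(0, σ_e²)` per plot.

## Numerical and reproducibility notes

- Every stochastic routine takes an explicit seed (`numpy.random.Generator`);
  CLI stage seeds derive from the master seed via
  `SeedSequence([master, stage_index])`, so stages rerun identically.
- Chain-length guidance: 2,000 iterations suffice for localization and
  segregation calls on study-sized data; conditional effect sizes at sharp
  peaks stabilize by ~4,000 iterations (adjacent-interval co-occupancy
  under the Poisson(2) prior attenuates shorter runs slightly).
- Known limitations: no dominance or epistasis; one QTL per 1-cM interval;
  no crossover interference in the generator or the bridge sampler;
  the contribution denominator includes between-family variance, so values
  are conservative relative to within-family definitions.
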