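# Methods

## Problem and model

National household health surveys often allocate an equal number of sample
clusters to every region to equalise standard errors across regions, even
though regional population sizes differ by an order of magnitude.
`surveysim` quantifies what that choice costs in overall accuracy, by
design-based simulation on a synthetic finite population whose truth is
known exactly.

The population has `H` strata (prefecture-like units), stratum `h`
containing `N_h` clusters (census enumeration areas), cluster `i`
containing `N_hi` households, household `j` containing `N_hij` members.
The continuous outcome `X` (modelled on systolic blood pressure, mmHg)
follows a four-level Gaussian hierarchy:

```
X_hijk ~ N(mu_hij, sigma_hij^2)      sigma_hij ~ N(10, 0.2^2)
mu_hij ~ N(mu_hi,  sigma_hi^2)       sigma_hi  ~ N(7,  0.2^2)
mu_hi  ~ N(mu_h,   sigma_h^2)        sigma_h   ~ N(5,  0.1^2)
mu_h   ~ N(130, 2.5^2)
```

with `N_h ~ U{4000..40000}`, `N_hi ~ round(N(50, 1))` floored at 1, and
`N_hij ~ U{1..6}`.  A binary indicator marks `X >= 140` (the hypertension
cutoff).  By the law of total variance the marginal variance of `X` is
approximately `2.5^2 + 5^2 + 7^2 + 10^2 = 180.25` (SD ≈ 13.4), and the
expected exceedance share is around 22%.

In **anchored mode** (`PopulationConfig.reference()`) the per-stratum
cluster counts and stratum means are fixed to the reference values built
into `population.py`, so that stratum weights — and therefore the design
comparison — do not depend on ten lucky draws of `mu_h` and `N_h`.  Only
the scale parameters and everything below them remain random.

## Sample designs

**Method 1 (conventional, equal allocation).**  Within each stratum,
`clusters_per_stratum` (default 100) clusters are drawn by systematic
random sampling without replacement from the stratum's cluster list, and
every household of a selected cluster is enumerated.  The individual-level
design weight in stratum `h` is the stratum's population size divided by
the realized sampled count, constant within the stratum; by construction
the weighted sample reproduces each stratum's size exactly.

**Method 2 (two-stage PPS).**  The whole cluster frame, sorted by
(stratum, cluster), is sampled in one pass with fixed-take systematic PPS,
size measure = household count; the sort gives implicit stratification, so
each stratum receives `n x (its household share)` clusters up to rounding
(±1 on every draw).  Within a selected cluster of `N` households,
`m = ceil(f N)` households are drawn by SRSWOR.  A household's weight is
`1 / (pi_cluster x m/N)` with `pi_cluster = n x N / (total households)`;
using the realized fraction `m/N` rather than the nominal `f` makes the
Horvitz–Thompson household-total estimator exactly design-unbiased under
the ceiling rule.  The standard scenarios pair `n` = 1000, 2000, 3000,
4000, 5000 with `f` = 1, 1/2, 1/3, 1/4, 1/5 so the expected household
take stays near 50 000.  Percent fractions are exact rationals (33% means
1/3).  Certainty units (`pi >= 1` strictly) are rejected rather than
taken with probability one: the standard scenarios never produce them, and
take-all handling would complicate the weight algebra for no gain here.

## Estimation

Means and proportions use the Hájek (weighted-ratio) form
`sum(w x) / sum(w)`, the form survey software reports for complex samples.
For Method 1 the Hájek and Horvitz–Thompson forms coincide because the
weights sum to the stratum sizes.  Under Method 2 the per-stratum figures
are *domain* estimates (strata are not design strata there); an empty
domain yields NaN and is counted by the simulation layer — impossible at
the standard scales, where the smallest stratum receives ≥ 20 clusters.
Households are always sampled intact, so estimation runs entirely on
precomputed household/cluster aggregates (member count, sum of X, sum of
the indicator); individual records are touched only when computing truth.

## Accuracy metric

For estimator `t` with truth `T` and replicates `t_1..t_R`,
`RMSE = sqrt(mean_r (t_r - T)^2)`, which satisfies
`RMSE^2 = Var_R + bias^2` with the divisor-R variance; the reported `sd`
column uses divisor R−1, hence the identity
`RMSE^2 = sd^2 (R-1)/R + bias^2` checked in the tests.  Truth is always
recomputed from the generated population, never taken from hyperparameters.
The Monte-Carlo CV of an RMSE estimate is roughly `1/sqrt(2R)` (≈ 2.2% at
R = 1000, ≈ 4% at R = 300).

## Randomness and determinism

The population is generated from its own seed with a documented draw order
(strata in order; within a stratum: counts, means, scales, then values),
so identical configs are bit-identical.  Sampling replicate `r` of design
stream `s` uses `SeedSequence(root_seed, spawn_key=(s, r))`: replicates
are independent, any execution order gives identical summaries, and a
single replicate can be regenerated in isolation.

## Numerical choices

- Scale draws are clamped at `1e-6` if nonpositive (probability ~0 under
  the default hyperpriors; the guard matters for user configs with large
  SDs).  Degenerate configs therefore produce values constant to ~1e-6,
  not bit-identical constants.
- Household counts: `round(N(50,1))` to the nearest integer, floor 1.
- Systematic sampling uses the fractional-interval rule by default
  (interval `k = frame/n` real, start uniform on `(0, k]`, positions
  `ceil(u + jk)`), which always returns exactly `n` units; integer
  ceil/floor interval rules are available and then realized size may
  deviate from `n` by one.
- Second-stage counts use `ceil(f N)` by default (`nearest` available),
  chosen because under the rounded-Normal(50,1) cluster-size distribution
  the ceiling rule reproduces the expected household takes of the
  benchmark scenarios.

## What the generator does and does not emulate

It emulates the *structure* that drives design performance: extreme
stratum-size imbalance, ~50-household clusters, within-cluster correlation
from shared cluster and household means.  It does not model nonresponse,
measurement error, non-Gaussian or categorical outcomes, geographic cost
of travel between clusters, or ratio estimation with auxiliary variables.
Passing tests therefore demonstrate properties of the *designs and
estimators* under a favourable, correctly-specified outcome model — not
robustness of any real survey's estimates.

## Problem sizes used in the tests

Unit tests run on miniature fixtures (a hand-enumerable 3-cluster
population; 4000 identical clusters for the closed-form variance oracle;
a two-stratum generated population; a 1/40-scale anchored population for
monotonicity).  The acceptance checks generate the full ~34M-individual
anchored population once and use R = 300 replicates per design
(R = 1000 in `scripts/acceptance.py`, matching the standard replicate
count).  The equal-cluster variance oracle uses 4000 clusters with n = 20
so that the systematic design's ~200 distinct samples concentrate its true
variance within a few percent of the SRSWOR formula `(1-n/N) S_b^2 / n`;
with few distinct samples that comparison is intrinsically noisy, which is
a property of systematic sampling, not an implementation artifact.

## Known limitations

- Joint inclusion probabilities of systematic PPS are not computed; the
  package reports Monte-Carlo accuracy, not per-sample variance estimates.
- Take-all (certainty) PPS units are rejected, not handled.
- Stratum-level results under Method 2 at small `n` are noisy domain
  estimates; the simulator reports them as-is.
- The simulator regenerates the population from config+seed instead of
  caching it to disk: generation is ~10 s at full scale and determinism
  makes a cache redundant; the config hash in the output JSON is the
  provenance link.
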