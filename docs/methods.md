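# Methods

## The sire model and its likelihood

Offspring of sire *i* are Bernoulli on the logit scale,

    P(y_ij = 1) = logistic(α + β_i),   β_i ~ N(0, τ²),

with no dam or bin terms in the default model (all larvae share one dam
and a common garden; replicate bins exist to randomize rearing, not as
a modelled factor — an additive bin fixed effect is available via
`bin_effect=True` but off by default). The marginal likelihood
integrates each sire's random effect out of the product of its
offspring's Bernoulli terms:

    L_i(α, τ²) = ∫ Π_j p(b)^{y_ij} (1 − p(b))^{1−y_ij} · N(b; 0, τ²) db.

Because offspring are individually genotyped larvae, the likelihood is
a Bernoulli product; binomial coefficients are omitted throughout (they
cancel in every likelihood-ratio comparison).

**Quadrature.** Each 1-D integral is evaluated by adaptive
Gauss–Hermite quadrature: the integrand's mode is located by a
safeguarded Newton iteration (step clipped to ±4, tolerance 1e-11), the
nodes are recentred there and rescaled by the curvature, and the sum is
accumulated in log space. Default `n_quad = 21` nodes; agreement with
scipy's adaptive 1-D integration is ≤ 1e-6 over α ∈ [−2, 2],
τ² ∈ [0, 5] on small datasets (asserted in the tests). At τ² = 0 the
exact closed-form Bernoulli log-likelihood is used, never a limit of
the quadrature. The inner kernel is numba-compiled: the permutation and
power machinery refit the model tens of thousands of times per run.

**Optimization.** The alternative model is maximized over (α, log τ²)
by Nelder–Mead (parameter tolerance 1e-6, function tolerance 1e-8, at
most 500 iterations), started from the pooled logit and a
method-of-moments variance of Haldane-corrected per-sire empirical
logits (clipped to [0.05, 5]). The boundary τ² = 0 is handled exactly,
not asymptotically: the interior optimum is compared against the
closed-form null fit (α̂ = pooled logit, τ² = 0), and whichever
likelihood is higher wins. This guarantees LRT = 2·Δloglik ≥ 0 and that
no-signal data return τ̂² = 0 exactly. Degenerate inputs raise: fewer
than two sires with offspring (no among-sire variance estimable), or
all-success/all-failure data (the intercept MLE diverges).

## Heritability transform

With logistic latent error (variance π²/3), the latent-scale variance
ratio is R² = τ²/(τ² + π²/3) ∈ [0, 1). Half-sibs share a quarter of the
additive genetic variance, so the sire-model narrow-sense heritability
is h² = 4R² ∈ [0, 4). The ×4 step is an approximation (it also absorbs
any dam-specific sire interactions, so strictly the estimate leans
toward broad sense) and can exceed 1; `h2` is reported unclamped with
an `h2_clamped` companion in [0, 1] used for presentation and for the
bootstrap CI. The inverse transform τ² = h²(π²/3)/(4 − h²) drives the
power simulator (round-trip exact to 1e-12).

## Bootstrap

Two resampling schemes are exposed:

* `offspring` (default): larvae are resampled with replacement within
  each sire × bin stratum. This conditions on the realized sires and
  quantifies within-sire sampling noise only — appropriate for "how
  variable is τ̂² given these nine sires".
* `sire` (sire-cluster): whole sire families are resampled with
  replacement (copies relabelled). This also propagates the sampling of
  sires from the population and is the scheme whose percentile CI
  attains nominal coverage of the population-level τ² (the test suite
  measures ≥ 90% coverage at 40 sires × 60 offspring; the offspring
  scheme materially undercovers there, by construction).

Replicates whose resample is all-success/all-failure or has fewer than
two sires cannot be fitted and are dropped and counted; more than 20%
dropped raises an unstable-bootstrap error. The 95% CI is the 2.5/97.5
percentile interval of the clamped h² replicates; `boot_sd` is the
standard deviation of the τ̂² replicates.

## Permutation test

The observed LRT is compared against refits on tables whose sire labels
are randomly reassigned across all offspring (each larva keeps its bin
and outcome; the label multiset is conserved). A within-bin shuffle is
available as an option. The p-value uses the add-one rule
(1 + #{T_perm ≥ T_obs})/(n_perm + 1), which is never zero; permuted
statistics within 1e-9 of the observed count as ties (conservative).
Default n_perm = 500. A single seeded `numpy` Generator drives the
shuffles, so results are bit-reproducible given the seed; a permuted
refit that fails to converge is retried from a perturbed start and
recorded as 0 with a logged warning if it persists (not observed in
practice — Nelder–Mead plus the exact boundary comparison always
terminates).

## Synthetic-data generator

The generator reproduces the statistical structure of the study:

| parameter        | default | meaning                                        |
|------------------|---------|------------------------------------------------|
| `n_sires`        | 9       | spawning colonies used as sires                 |
| `n_bins`         | 3       | replicate culture bins                          |
| `mu_offspring`   | 4.63    | mean genotyped offspring per sire per bin       |
| `var_offspring`  | 12.63   | variance of that count (NB size = μ²/(σ²−μ))    |
| `p_settle`       | 0.285   | baseline settlement probability (global mean)   |
| `tau2`           | 0       | true among-sire variance on the logit scale     |

Counts per sire × bin are negative binomial; each offspring settles
independently with probability logistic(logit(p_settle) + β_i), β_i
drawn once per sire (β_i = 0 under the null, so the only among-sire
variability is sampling). `p_settle` is placed on the conditional
(latent) scale by default, so the marginal settlement rate deviates
slightly from it when τ² > 0; `marginal_p=True` instead solves for the
intercept that matches the marginal mean (Gauss–Hermite + Brent).
Zero-count cells are kept (a sire can contribute no offspring in a
bin); a simulated dataset with fewer than two sires with offspring, or
with no successes or no failures, cannot be fitted and is resimulated
with a logged count. When the mean offspring number is varied in power
studies, the variance:mean ratio is held at the study value 12.63/4.63.

What the generator does **not** emulate: dam effects (one dam), bin
(culture) effects on settlement, genotyping failure and paternity
ambiguity (it produces true sire labels), and non-Gaussian sire
effects. Passing tests therefore show the statistical machinery is
correct and well calibrated under the stated design, not that real
data meet these assumptions.

## Null distribution, power, and the asymptotic mixture

`null_lrt_distribution` fits both models to each of `n_datasets` null
simulations and returns the LRT sample with its right-continuous ECDF;
the boundary produces a large point mass at zero (over 40% — indeed
≈ 75% at the study design, versus the 50% the asymptotic theory
assigns). The asymptotic reference, 0.5·δ₀ + 0.5·χ²(1), is implemented
as `theoretical_mixture_cdf`. On study-shaped data the mixture CDF lies
below the actual-null ECDF through the upper tail — the asymptotic test
is conservative — while the permutation null from even a single dataset
is closer in Kolmogorov–Smirnov distance (both properties asserted in
the acceptance tests with 1000 null simulations).

`power_analysis` runs the full permutation test on every simulated
dataset and reports the rejection fraction at α (power for τ² > 0
designs, false-positive rate for null designs) with its binomial Monte
Carlo standard error. The default rejection threshold is α = 0.05.
Problem sizes: the acceptance checks use 200 datasets × 200
permutations per design (and 1000 datasets for the null-CDF
comparison), chosen as the smallest sizes at which the Monte Carlo
error is well inside the margins being asserted; the library defaults
remain 1000 × 500.

## Parentage computations

Per-locus allele frequencies are counted over the panel's allele copies
(two per diploid call). PI uses the naive unrelated-individuals form
PI = 2(Σp²)² − Σp⁴ — equal to the sum of squared Hardy–Weinberg
genotype probabilities, as the brute-force oracle in the tests checks —
and multiplies across loci assuming independence; no sibling correction
and no sample-size correction (the uncorrected form reproduces both
panel endpoints, 3.2E-01 and 2.0E-06). Multilocus-genotype grouping
compares unordered allele pairs exactly (sizes are pre-binned
integers); missing loci mismatch unless the wildcard flag is set.
Paternity is exclusion-based: a sire is compatible when it carries at
least one offspring allele at every amplified locus (the dam being
ungenotyped in the design); supplying a dam genotype switches to the
stricter Mendelian partition rule. Offspring amplifying at fewer than
`min_loci = 3` loci (i.e. not more than 2) are excluded; exactly one
compatible sire makes an assignment, several an abstention. No
likelihood-based (LOD) assignment, genotyping-error or null-allele
modelling.

## Known limitations

* Single random effect only: no dam, dam × sire, or pedigree (animal
  model) terms, and no REML — by design, matching the one-dam
  common-garden layout.
* The ×4 transform can exceed h² = 1 and conflates sire-linked
  non-additive variance with additive variance.
* The permutation test's empirical size at the study design is close to
  but not exactly the nominal α (the test suite asserts validity within
  Monte Carlo slack, not exactness).
* Nelder–Mead with the boundary comparison is robust but not gradient
  -accelerated; fits on thousands of sires are still fast (< 0.1 s) but
  not instant.
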