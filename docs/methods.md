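# Methods

`rarecausal` implements two complementary strategies for pinpointing rare
causal variants in a sequenced region (a gene), on top of the standard
gene-level association machinery, plus a simulation framework that generates
cohorts with known causal structure for benchmarking.

## Groupwise score tests

For `n` individuals with trait `y`, covariates `X` and an `n x m` dosage
matrix `G` (minor-allele counts), the null GLM `g(E[y]) = alpha_0 + X alpha`
(logit link for dichotomous traits, identity for continuous) yields fitted
means `mu` and per-variant scores `S_j = sum_i G_ij (y_i - mu_i)`.  With
non-negative weights `w` the exchangeable family

    Q_rho = rho (sum_j w_j S_j)^2 + (1 - rho) sum_j (w_j S_j)^2

interpolates between the Burden statistic (`rho = 1`; one squared weighted
sum, most powerful when effects are unidirectional and of similar size) and
SKAT (`rho = 0`; robust to mixed directions and sparse signals).  Under the
null, `S ~ N(0, Phi)` asymptotically with `Phi = G' P0 G`,
`P0 = V - V X (X' V X)^{-1} X' V`, `V` the GLM variance diagonal, so `Q_rho`
is distributed as a mixture of chi-square(1) variables with weights equal to
the eigenvalues of `A^{1/2} Phi A^{1/2}`, `A = rho w w' + (1 - rho) diag(w^2)`.

Two tail evaluators are provided:

* `moment_match` (default): the Liu-type fit of a (non)central chi-square by
  mean, variance and skewness or kurtosis, exactly as used by the standard
  SKAT implementations.  It is smooth, fast, and has no integration failure
  modes.  Its known weakness is the far tail: against the exact inversion it
  is within a few percent for p >= 1e-3 but can deviate by 10-25% around
  p = 1e-4, which is why the agreement test bounds 10% only down to 1e-3.
* `davies`: Imhof's characteristic-function inversion.  The oscillatory
  integral is evaluated by a composite 12-point Gauss-Legendre rule over
  segments of one oscillation period (the phase rate is bounded by
  `(Q + sum lambda)/2`), truncated where the amplitude envelope
  `1/(u rho(u))` times the segment length falls below 1e-13; below p = 1e-14
  the inversion is numerically meaningless and the moment-matched tail is
  returned.  This evaluator reproduces exact chi-square tails to ~10 digits
  and 200,000-replicate Monte Carlo references to Monte-Carlo precision.

Defaults: flat weights `w_j = 1` (a Beta(1,25) MAF weighting is available via
`beta_maf_weights`); variants with sample MAF above 0.05 are excluded from
grouped analyses by the pipeline (the rare-variant regime is where these
tests are meant to operate); missing dosages are mean-imputed per variant,
which preserves each column's allele frequency; all-zero columns are dropped
with a warning.  Monomorphic-trait or separated null fits raise errors rather
than returning degenerate results.

## Backward elimination and return counts

Given a variant set, the elimination step computes the groupwise p-value,
tentatively deletes each variant in turn, and permanently removes the one
whose deletion lowers the p-value most; it stops when no deletion improves
the current p-value and returns the surviving set.  Deleting a causal variant
tends to *raise* the reduced-set p-value, so causal variants survive.
Ties at the argmin are broken by the smallest variant index, making runs
deterministic.  A set shrinking to one variant terminates as that singleton.

Because one weak variant's contribution to a large set is hard to assess, the
procedure is applied to 2000 random subsets of `k = 10` variants (both
configurable; subsets are drawn uniformly without replacement within a
resample and may repeat across resamples).  A variant's *return count* is the
fraction of subsets containing it in which it survived; raw tallies are kept
alongside.  The same fitted null model is reused for every subset (it does
not involve genotypes), and for the default Burden statistic each elimination
step uses closed-form downdates of the weighted score sum and its single null
eigenvalue, so a full 2000-resample run on a ~40-variant stratum takes on the
order of a second.  The procedure is run separately within the functional
(non-synonymous, nonsense, splice, frameshift) and synonymous strata; one
annotation score at a time may be supplied as the weight vector inside the
test.

## Classifying return counts

The return-count sample is split into "non-interesting" and "interesting"
groups with a two-component mixture whose component densities are weighted
Gaussian kernel density estimates (bandwidth: Silverman's rule on the pooled
sample, fixed across iterations).  Two numerical points deserve emphasis:

* A univariate nonparametric two-component mixture is not identifiable: the
  EM map has an attracting degenerate fixed point at which both component
  densities equal the pooled density and every responsibility equals the
  mixing proportion.  A soft EM demonstrably drifts into it from any
  initialization.  We therefore run the *classification* EM: the M-step
  re-estimates proportions and kernel densities from the current hard
  partition, the E-step reassigns each observation to the component with
  maximal responsibility, and iteration stops when the partition is stable.
  Its fixed points are stable partitions with no leakage path.
* Initialization is the exact 1-D 2-means partition (minimum within-cluster
  sum of squares), which is deterministic and recovers the generating labels
  on separated clusters regardless of the upper-cluster fraction.

The "interesting" label goes to the component with the larger mean return
count.  The fit declares *no separation* when the smaller component holds
under 2% of the sample, the component means are closer than one pooled SD, or
the pooled density has no valley between the component means (a hard split of
a unimodal sample still produces means ~1.6 SD apart, so the valley check is
what actually detects unimodality).  Without separation, selection falls back
to the top-20% return-count rule (boundary ties all included), which is also
the default for the synonymous stratum, where return counts rarely form two
groups.

## Hierarchical model

Stage one relates the trait to genotypes and confounders,
`logit P(y_i=1) = alpha_0 + x_i' alpha + g_i' beta`; stage two relates the
per-variant log odds ratios to variant-level annotations,
`beta = Z gamma + b`, `b ~ N(0, tau^2 I)`, where `Z` (always including an
intercept; constant columns are dropped) may hold the non-synonymous
indicator, binary damaging flags, or continuous conservation scores, used
unstandardized so `gamma` is interpretable per score unit.  Missing scores
are imputed as 0, matching the convention that synonymous/unscored variants
carry a predictor of 0.  Substitution gives the logistic mixed model
`logit P(y=1) = alpha_0 + X alpha + G Z gamma + G b`.

Estimation is a hybrid of Bayesian and pseudo-likelihood steps:

* **Variance component.**  For each `tau^2` on a geometric grid of 40 points
  in [1e-4, 4] (log-OR variance scale), the joint penalized logistic fit in
  the augmented design `[X | GZ | G]` (ridge penalty `1/tau^2` on the `b`
  block only) provides a Laplace-approximated marginal likelihood
  `l(theta_hat) - b_hat'b_hat/(2 tau^2) - log det(tau^2 S + I)/2`, where `S`
  is the Schur complement of the fixed-effect block in the observed
  information (so fixed-effect estimation is accounted for).  Combined with a
  half-normal prior on `tau` (scale 1) and trapezoid weights, this yields a
  grid posterior whose mean is `tau^2_hat`.  A posterior peaking at the upper
  grid edge triggers a warning to extend the grid.
* **Effects.**  With `tau^2_hat` fixed, the same ridge-penalized Newton fit
  (equivalent to penalized quasi-likelihood at convergence for this model
  shape) gives `alpha_hat`, `gamma_hat`, `b_hat`; per-variant effects are
  `beta_hat_j = (Z gamma_hat)_j + b_hat_j` with standard errors propagated
  through the inverse penalized observed information.  Sparse variants are
  shrunk toward their annotation prediction `Z gamma_hat`; variants with many
  carriers override a misleading annotation (their own likelihood dominates).

At `tau^2 = 0` with intercept-only `Z` the model collapses exactly to the
common-effect burden-collapsing logistic regression, which the tests verify
against an independent fit to 1e-6.  Continuous traits are supported through
the identity link with a Gaussian residual variance and are flagged
experimental; the dichotomous path is the primary, tested one.  Variants are
ranked by `beta_hat` (default) or by `z = beta_hat / se`, ties broken by
variant id; the headline usage ranks only the backward-elimination-selected
variants but fits the model on all rare variants.

## Synthetic cohorts

The generator emulates the statistical structure of a rare-variant
case-control study of one region:

* **Haplotype pool.**  10,000 haplotypes over a 1 Mb region with 10,000
  sites; per-site minor-allele counts follow the neutral site-frequency
  spectrum P(count = i) proportional to 1/i, carriers assigned uniformly.
  Analyses use random 10 kb subregions (~100 sites each).  Externally
  simulated haplotypes (e.g. coalescent output) can be imported.
* **Disease models.**  Causal variants get odds ratios as a decreasing step
  function of MAF.  Defaults: M1 = OR 3.0 (MAF < 0.001), 2.0 (0.001-0.01),
  1.5 (0.01-0.05); M2 = 5.0/3.0/2.0 on the same bins.  These are this
  package's calibration of the usual "strong effects for the rarest
  variants" regime (M2 deliberately stronger than M1); the OR values and bin
  edges are configuration data, not code.  By default 20% (alternatively
  10%) of the variants with MAF <= 0.05 in the region are causal.
* **Phenotypes.**  `logit P(y=1) = beta_0 + sum_j beta_j g_j` with `beta_0`
  calibrated by bisection (on a fixed 200,000-genotype Monte-Carlo sample, so
  the solve is deterministic and monotone) to a population prevalence of
  0.05.  Cohorts of 1000 cases and 1000 controls (n = 2000) accrue by
  rejection sampling of random haplotype pairings; homozygous rare carriers
  arise at Hardy-Weinberg rates.
* **Annotations.**  80% of causal variants are non-synonymous; the
  non-synonymous share of non-causal variants follows from Bayes' rule given
  the region's NS:S ratio (0.6, 1.0 or 1.4).  Non-synonymous variants carry
  binary predictors drawn independently given causal status: a moderate
  "damaging" flag B1 (80% causal / 30% non-causal), a high-specificity
  "probably damaging" flag B2 (80% / 10%), and a non-informative flag
  (50% / 50%); synonymous variants carry 0.

What the generator does *not* emulate — and hence what passing benchmarks do
not demonstrate about real data: linkage disequilibrium and haplotype block
structure, demographic-model site-frequency distortions, genotyping or
sequencing error, population stratification, correlated or continuous-valued
annotation errors, and winner's-curse effects from genome-wide scanning.
The benchmark numbers characterize the methods under the stated generating
conditions only.

## Benchmark studies and evaluation

Replicate studies (`run_simulation_study`) simulate cohorts, apply the
gene-level Burden gate (alpha = 0.05 by default; the selection and effect
machinery is meant for genes already showing association, so gated-out
cohorts are skipped and further regions drawn — estimates are therefore
conditional on gene-level significance, which contributes a small upward
bias), run the stratified backward elimination, the mixture/quantile
selection, and one hierarchical fit per annotation set under comparison.

Metrics: the median 1-based rank of causal variants in a ranking and the
causal count among the top 10, summarized across replicates by the *lower*
median (deterministic for integer inputs); mean absolute error and nominal-95%
Wald coverage of `beta_hat` pooled over variants and replicates; ROC curves
(via scikit-learn) comparing the model ranking against an annotation score
alone.  Desk-scale defaults use 50 replicates of n = 2000; all summaries
carry Monte-Carlo standard errors.

## Known limitations

* The Wald intervals take `tau^2_hat` as fixed; variance-component
  uncertainty is not propagated (full MCMC is out of scope).
* The exchangeable-`rho` family is evaluated at a user-fixed `rho`; there is
  no omnibus optimization over `rho`.
* Effect estimates inherit hierarchical shrinkage bias: non-causal variants
  with high scores are pulled up, sparse causal variants with low scores are
  pulled down; this grows with the true effect sizes (stronger under M2).
* The sample-MAF rare-variant filter can exclude a causal variant whose
  case-enriched sample frequency drifts above the threshold.
* Family-based designs, scan statistics and external annotation computation
  are out of scope; the package consumes annotation scores as given.
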