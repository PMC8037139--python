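# Methods

## The model

`bgindex` fits a Bayesian group index regression for a binary health outcome
against mixtures of correlated chemical exposures. For subject *i* with
outcome *y<sub>i</sub>* ~ Bernoulli(*p<sub>i</sub>*),

logit(*p<sub>i</sub>*) = β₀ + Σ<sub>k=1..K</sub> β<sub>k</sub>
(Σ<sub>j=1..C_k</sub> w<sub>jk</sub> q<sub>ijk</sub>) + **z**<sub>i</sub>ᵀφ

where *q<sub>ijk</sub>* ∈ {0, …, Q−1} is the quantile score of chemical *j*
in group *k* (quartiles, Q = 4, by default), the weights **w**<sub>k</sub> of
each group lie on the probability simplex, β<sub>k</sub> is the log odds
ratio for a one-quantile increase of the whole group-*k* index, and φ holds
covariate effects. Working on quantile scores tames outliers and removes the
arbitrary concentration scales of different assays; constraining the weights
to a simplex makes (β<sub>k</sub>, **w**<sub>k</sub>) jointly identified
(no sign-flip ambiguity exists) and lets the weights be read as relative
importance within the group. Groups are chosen by the analyst — typically
chemical families (PCBs, insecticides, metals, …) — and each group carries
its own effect direction and magnitude, which a single weighted index cannot
do.

### Priors

* **w**<sub>k</sub> ~ Dirichlet(α<sub>k</sub>), default α = (1, …, 1): uniform
  on the simplex. Informative α can be supplied per group.
* β₀, β<sub>k</sub>, φ ~ Normal(0, sd = 10) by default. On the log-odds scale
  sd 10 is effectively flat while keeping the posterior proper. Two variants
  are exposed: `flat_intercept=True` drops the intercept prior (improper
  flat), and `hierarchical_sigma=True` replaces the fixed sd with one sampled
  scale per coefficient, σ ~ Uniform(0, 100), adding a Metropolis block on
  log σ. All coefficients are treated identically under the hierarchy.

Categorical covariates are dummy-coded against a reference level; rows with
missing covariates are dropped (complete-case analysis).

### Data preparation

Quantile scores: subjects are ranked per chemical (ties receive the average
rank, so tied concentrations always share a score) and cut at the empirical
1/Q, …, (Q−1)/Q quantiles of the analysis sample itself:
score = ⌊Q·rank/(n+ε)⌋. Scores are invariant under strictly monotone
transforms, and for n divisible by Q with no ties every level holds exactly
n/Q subjects. Cut points are computed on the pooled analysis sample
(cases + controls jointly).

Below-LOD concentrations: a lognormal is fitted by maximum likelihood
treating below-LOD entries as left-censored (each contributes
Φ((log LOD − μ)/σ) to the likelihood — a fitted distribution, not LOD/√2
substitution), and censored entries are replaced by inverse-CDF draws from
that lognormal truncated to (0, LOD). Chemicals detected in fewer than 20%
of samples are refused with an error advising exclusion, the usual inclusion
rule. Imputation is univariate per chemical; multivariate or model-based
multiple imputation is out of scope.

## Posterior computation

Metropolis-within-Gibbs with these blocks: one random-walk block per weight
simplex on its additive log-ratio (ALR) transform z<sub>j</sub> =
log(w<sub>j</sub>/w<sub>C</sub>) (log-Jacobian Σ log w<sub>j</sub> included;
proposals stay strictly interior), one joint block for (β₀, β), one for φ,
and one for the hierarchical log σ when enabled. Two chains run from
overdispersed starts (weights from Dirichlet(α/2)-style draws, coefficients
from Normal(0, 2)) with independent spawned seed streams; runs are bitwise
reproducible given the seed.

During burn-in only, each block's proposal is tuned two ways: Robbins-Monro
scaling of a global step size toward a 0.35 acceptance rate, and
Haario-style shaping by the running (Welford) covariance of the block's own
draws, switched on after 150 burn-in draws and refreshed every 50. The
shaping matters: the intercept and index effects are strongly correlated a
posteriori, and the weight log-ratios are strongly anisotropic (a chemical
with posterior weight near zero has a diffuse log-ratio), so spherical
proposals mix an order of magnitude more slowly. All tuning freezes at the
end of burn-in, so the retained chain is Markov. Non-finite log-posterior at
a start triggers a bounded number of fresh draws.

### Convergence

The Gelman-Rubin potential scale reduction factor is computed per scalar
parameter with the degrees-of-freedom correction and a 97.5% F-quantile
upper bound (the classic formulation; our implementation agrees with R
`coda::gelman.diag` to printed precision), by default on split half-chains so
within-chain trends also register. Weight simplices are diagnosed on
within-group log ratios, the unconstrained scale the sampler moves on.
Convergence is declared when every upper bound is below 1.10. A Geweke
z-score (default windows: first 10% vs last 50%) with Bartlett-windowed
spectral standard errors (lag ≈ √n) is available as a single-chain check.

Default run length is 15,000 iterations with 5,000 burn-in. This is not
generous padding: at this sampler's autocorrelation (effective sample size
roughly 200–450 per 8,000 retained draws for the coefficient block), the
F-quantile upper bound needs on the order of 10,000 retained draws per chain
to fall below 1.10 reliably; at 4,000 retained draws per chain it exceeded
1.10 in roughly 40% of otherwise well-behaved replicate fits. Shorter chains
are fine for exploration but will (correctly) trip the convergence flag.

### Reported summaries

Odds ratios are posterior means of exp(β) with equal-tailed 95% credible
intervals (2.5%/97.5% posterior quantiles — quantile intervals, not HPD,
matching how such tables are conventionally printed); an effect is flagged
significant when its interval excludes 1.00. Chemical importance uses the
posterior-mean weight against the equal-share threshold 1/C<sub>k</sub>,
boundary inclusive (weight ≥ 1/C<sub>k</sub> ⇒ important); the threshold is
applied to the mean weight, not to per-draw probabilities.

## The GWQS comparator

The frequentist two-step grouped WQS baseline: (1) split the data 40/60 into
training and validation parts, stratified on the outcome; (2) on 100
bootstrap resamples of the training part, maximize the logistic likelihood
jointly in (β₀, β, **w**, φ) with each **w**<sub>k</sub> constrained to its
simplex — SLSQP with analytic gradients, bounds [0, 1], one sum-to-one
equality per group, 3 multistarts per resample — and average the replicate
weights, weighted by the |z| statistic of the replicate's index effect from
an unconstrained logistic refit on its constructed indices (the usual WQS
"signal-weighted" convention; plain averaging via
`signal_weighted=False`); (3) fit ordinary logistic regression of the
outcome on the fixed-weight indices in the validation part and report Wald
95% confidence intervals. Failed bootstrap replicates are dropped with a
warning; complete separation in the validation fit is flagged and yields
infinite interval bounds rather than an exception. The 40% training
fraction, bootstrap count and aggregation rule are the original WQS
package conventions; numerical equivalence with any particular R
implementation's optimizer is not a goal — equivalence is statistical.

## Simulation study

The generator emulates a balanced case–control study of chemical mixtures.
Exposures are multivariate normal with exchangeable block correlation
(weak 0.5/0.1, moderate 0.7/0.3, strong 0.9/0.5 within/across groups) and
standard normal marginals — location and scale are irrelevant because
quantization erases them. Scenario sets fix the group structure (A: 9
chemicals in groups of 5/4 with 2/2 important, n=1000; B: 14 in 5/4/5 with
1/1/1, n=1000; C: as B with 3/2/3 important; D: as C with n=500) and five
strength levels fix true odds ratios per group (group 1 negative, the rest
positive; A–C: 1.50/2.00/2.50/3.00 and reciprocals; D: 1.25/1.50/1.75/2.00
and reciprocals; level 1 is the global null). Important chemicals are the
leading ones of each group and share the group weight equally; unimportant
chemicals have true weight exactly zero.

Within each replicate, quartile scores are computed from that replicate's
own exposures (as one would with real data), the linear predictor uses the
true weights and effects, and the intercept is calibrated as
β₀\* = −(Q−1)/2 · Σβ<sub>k</sub>\* so the expected case fraction is one
half; a dataset is accepted only when its case fraction lies in [0.40,
0.60], otherwise the outcome is redrawn (bounded retries; exhaustion raises,
signalling a miscalibrated intercept). No covariates enter the generator.

Across replicates the harness reports: power / type-I error (proportion of
95% intervals excluding 1.00), bias and MSE of the estimated ORs — on the OR
scale by default, since that is the scale on which MSE magnitudes of ~0.01
arise at OR errors of ~0.03–0.07; a log-scale option exists — and
sensitivity/specificity of the importance calls at 1/C<sub>k</sub>, pooled
over chemicals and replicates. Replicates are independently seeded from a
master seed, rerunnable bit-for-bit, and fit failures are recorded rather
than dropped.

### What the generator does and does not emulate

It reproduces the correlation structure, group sizes, effect sizes, sample
sizes and case–control balance of the study design. It does not emulate
below-LOD censoring, missing covariates, confounding, measurement error, or
non-normal concentration distributions (irrelevant to quantile scores except
through tie structure). Passing tests therefore demonstrate estimator
behaviour under the stated design, not robustness to those real-data
features.

### Desk-scale settings

Replicate runs in the test suite and the acceptance script use 25 replicates
per condition (the full study used 100) with full-length 15,000/5,000
chains; proportions estimated from 25 replicates carry a Monte-Carlo
standard error of up to ±0.10, and the checks use ±0.15 bands for
proportions and ±0.06 for replicate-mean odds ratios. A complete
three-condition run takes roughly 12–15 minutes on one CPU.

## Numerical choices and degenerate inputs

* Bernoulli log-likelihood via log(1+e^η) = logaddexp(0, η); finite for all
  finite parameters.
* Weights outside the simplex get log-prior −∞ (a rejected state, never an
  exception); Dirichlet densities with any α<sub>j</sub> < 1 require strictly
  interior weights.
* Simplex validity tolerance 1e-10 on Σw = 1; posterior-mean weights sum to
  1 within 1e-6 per group.
* A constant exposure column is an error naming the chemical (its quantiles
  are undefined); Q > n is an error; a single-chemical group has weight
  fixed at 1 and no sampler block.
* A group index constant across the validation part makes the GWQS effect
  inestimable and raises; bootstrap resamples that lose an outcome class are
  counted as failed replicates.
* SLSQP tolerance 1e-8; weights are clipped to [0, 1] and renormalized after
  optimization to remove O(tol) constraint violations.

## Known limitations

* Subject-level and spatial random effects, penalized or mixture priors on
  the index effects, and lasso-type comparators are out of scope.
* The importance threshold 1/C<sub>k</sub> treats groups of very different
  sizes asymmetrically; with weak signal, posterior-mean weights shrink
  toward 1/C<sub>k</sub> under the uniform Dirichlet prior, so
  sensitivity/specificity hover near chance under the null — a property of
  the estimand, visible in the null-scenario metrics.
* GWQS interval coverage depends on the split; only Wald intervals from the
  validation fit are implemented (bootstrap intervals are not).
* The Metropolis sampler is slower per effective draw than gradient-based
  samplers; the adaptive blocks mitigate but do not remove this.
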