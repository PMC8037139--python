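# bgindex — Bayesian group index regression for chemical mixtures

People are exposed to dozens of correlated environmental chemicals at once,
and epidemiologic studies of cancer and other outcomes increasingly need to
estimate the joint effect of whole chemical families — insecticides, PCBs,
PAHs, metals — rather than one chemical at a time. Strong within-family
correlation makes ordinary multi-chemical logistic regression unstable, and
single-index weighted quantile sum (WQS) regression forces every chemical
into one index with one direction of effect.

`bgindex` implements **Bayesian group index regression**: a logistic model
with one weighted quantile-sum index per chemical group,

&nbsp;&nbsp;&nbsp;&nbsp;logit(p_i) = β₀ + Σ_k β_k (Σ_j w_jk q_ijk) + z_iᵀφ

where q_ijk ∈ {0,…,Q−1} are within-sample quantile scores (quartiles by
default), each group's weights w_k live on the probability simplex under a
Dirichlet prior, β_k is the log odds ratio per one-quantile increase of the
group-k index, and φ are covariate effects. Each group gets its own effect
direction and magnitude in a single one-step fit by MCMC — no
training/validation split — and the posterior weights rank the chemicals
within each group (a chemical is "important" when its mean weight reaches
the equal-share threshold 1/C_k).

The package is aimed at environmental epidemiologists and biostatisticians
and also ships:

* the frequentist **two-step grouped WQS comparator** (stratified split,
  bootstrap weight estimation by simplex-constrained maximum likelihood,
  validation-set logistic fit),
* below-LOD **censored-lognormal imputation** and quantile scoring,
* **Gelman-Rubin** (with upper confidence bound) and **Geweke** convergence
  diagnostics,
* a **simulation harness** for power, bias, MSE, sensitivity and specificity
  under block-correlated exposure scenarios, and
* a `bgindex` CLI (`fit`, `gwqs`, `simulate`, `report`) over CSV inputs.

See `docs/methods.md` for the model, priors, sampler and simulation design
in detail.

## Worked example

Simulate one case–control study from a built-in scenario (n=500 subjects,
14 chemicals in three groups of 5/4/5 with 3/2/3 truly important chemicals,
true odds ratios 0.67 / 1.50 / 1.50, moderate correlation: 0.7 within group,
0.3 across) and fit the model:

```python
import bgindex as bg

scenario = bg.build_scenario("D", 3, "moderate")
data = bg.generate_dataset(scenario, seed=1)

model = bg.BayesianGroupIndex(data.y, data.quantiles, data.groups)
res = model.fit(n_iter=15000, n_burnin=5000, seed=3)
print(res.summary())
```

```
Bayesian group index regression (logit link)
============================================================
Subjects: 500    Groups: 3    Chains: 2    Retained draws/chain: 10000
Max PSRF upper bound: 1.0338 (converged, criterion < 1.10)

Odds ratios (posterior mean, equal-tailed 95% credible interval)
------------------------------------------------------------
  g1                         0.744  ( 0.598,  0.925) *
  g2                         1.503  ( 1.207,  1.850) *
  g3                         1.509  ( 1.215,  1.839) *

Chemical weights (posterior mean; '*' = at or above 1/C_k)
------------------------------------------------------------
  g1           x1_1                  0.202 (threshold 0.200) *
  g1           x1_2                  0.423 (threshold 0.200) *
  g1           x1_3                  0.118 (threshold 0.200)
  g1           x1_4                  0.150 (threshold 0.200)
  g1           x1_5                  0.106 (threshold 0.200)
  ...
```

Reading this: all three group effects are significant (intervals exclude
1.00) and estimated near their true values 0.67/1.50/1.50. In group 1 the
truly important chemicals are x1_1–x1_3 (true weight 1/3 each); on this
single replicate the posterior splits their shared signal unevenly — x1_1
and x1_2 clear the 1/C₁ = 0.2 threshold, x1_3 does not — which is exactly
why the simulation study measures importance classification as sensitivity
and specificity across many replicates rather than from one study. The
maximum Gelman-Rubin upper bound below 1.10 certifies the two chains mixed.

The frequentist comparator on the same data:

```python
gw = bg.GroupWQS(data.y, data.quantiles, data.groups).fit(bg.GWQSConfig(seed=5))
print(gw.summary())
```

```
Grouped WQS regression (two-step)
============================================================
Odds ratios (validation fit, Wald 95% CI)
------------------------------------------------------------
  g1                         0.883  ( 0.696,  1.120)
  g2                         1.571  ( 1.194,  2.067) *
  g3                         1.285  ( 0.997,  1.657)
```

On this replicate the two-step split costs GWQS the group-1 and group-3
signals that the one-step Bayesian fit detects — the power gap the
simulation study quantifies.

From the command line the same runs are driven by YAML configs over CSV
inputs (`bgindex fit --config fit.yaml`, `bgindex simulate --config
sim.yaml`); every output table carries the config hash and seed, exit code 2
flags convergence failure, and 3 flags input errors.

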