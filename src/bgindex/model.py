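"""Bayesian group index regression: likelihood, priors, and the model class.

The model is a logistic regression on K weighted quantile-sum indices,
one per chemical group::

    logit(p_i) = beta0 + sum_k beta_k * (sum_j w_jk q_ijk) + z_i' phi

where q_ijk is the quantile score (0..Q-1) of chemical j in group k for
subject i and the weights w_k of each group live on the probability simplex
(w_jk >= 0, sum_j w_jk = 1) under a Dirichlet prior. The index effect beta_k
is the log odds ratio for a one-quantile increase of the whole group-k index;
the weights apportion that effect among the group's chemicals. Because the
weights are nonnegative and sum to one, (beta_k, w_k) are jointly identified:
no sign-flip ambiguity exists.

Priors: Dirichlet(alpha) on each weight simplex (alpha = 1 by default, i.e.
uniform) and vague normals on beta0, beta_k and phi. A hierarchical variant
with a Uniform(0, s_max) prior on each coefficient's prior standard deviation
is available via ``PriorSpec(hierarchical_sigma=True)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data import (
    GroupStructure,
    QuantileMatrix,
    StudyData,
    build_group_structure,
    quantize_exposures,
    ExposureTable,
)

__all__ = [
    "ModelParams",
    "PriorSpec",
    "compute_indices",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "BayesianGroupIndex",
]

_SIMPLEX_TOL = 1e-10


@dataclass
class ModelParams:
    """One point in parameter space.

    beta0: intercept; betas: K index effects (log odds ratios); weights: one
    simplex vector per group, length C_k each; phi: covariate effects.
    """

    beta0: float
    betas: np.ndarray
    weights: list[np.ndarray]
    phi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.betas = np.atleast_1d(np.asarray(self.betas, dtype=float))
        self.weights = [np.asarray(w, dtype=float) for w in self.weights]
        if self.phi is not None:
            self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
            if self.phi.size == 0:
                self.phi = None
        if len(self.weights) != self.betas.shape[0]:
            raise ValueError("one weight vector required per index effect")

    def weights_valid(self, tol: float = _SIMPLEX_TOL) -> bool:
        for w in self.weights:
            if np.any(w < 0) or abs(w.sum() - 1.0) > max(tol, 1e-8):
                return False
        return True


@dataclass
class PriorSpec:
    """Prior hyperparameters.

    dirichlet_alpha: per-group concentration vectors; None means all-ones
    (uniform on each simplex). beta_prior_sd / phi_prior_sd: standard
    deviations of the vague normal priors on the intercept and index effects,
    and on covariate effects. hierarchical_sigma puts sigma ~ Uniform(0,
    sigma_upper) on each coefficient's prior sd instead of fixing it;
    flat_intercept drops the intercept prior entirely (improper flat).
    """

    dirichlet_alpha: list[np.ndarray] | None = None
    beta_prior_sd: float = 10.0
    phi_prior_sd: float = 10.0
    hierarchical_sigma: bool = False
    sigma_upper: float = 100.0
    flat_intercept: bool = False

    def alphas_for(self, groups: GroupStructure) -> list[np.ndarray]:
        if self.dirichlet_alpha is None:
            return [np.ones(c) for c in groups.sizes]
        alphas = [np.asarray(a, dtype=float) for a in self.dirichlet_alpha]
        if len(alphas) != groups.n_groups:
            raise ValueError("one Dirichlet alpha vector required per group")
        for a, c in zip(alphas, groups.sizes):
            if a.shape != (c,):
                raise ValueError("alpha length must match group size")
            if np.any(a <= 0):
                raise ValueError("Dirichlet concentrations must be positive")
        return alphas


def compute_indices(q: QuantileMatrix, groups: GroupStructure,
                    weights: list[np.ndarray]) -> np.ndarray:
    """Weighted quantile-sum index per subject and group, entries in [0, Q-1].

    Entry (i, k) is sum_j w_jk * q_ijk over the chemicals j of group k.
    """
    if q.chemical_ids is None:
        cols = _default_columns(groups)
    else:
        cols = groups.member_indices(q.chemical_ids)
    n = q.n_subjects
    K = groups.n_groups
    out = np.empty((n, K))
    qf = q.q.astype(float, copy=False)
    for k in range(K):
        w = np.asarray(weights[k], dtype=float)
        if w.shape != (groups.sizes[k],):
            raise ValueError(
                f"group {k}: {w.shape[0]} weights for {groups.sizes[k]} chemicals"
            )
        out[:, k] = qf[:, cols[k]] @ w
    return out


def _default_columns(groups: GroupStructure) -> list[np.ndarray]:
    """Group -> column map when the quantile matrix carries no chemical ids:
    columns are assumed ordered group by group."""
    cols = []
    start = 0
    for c in groups.sizes:
        cols.append(np.arange(start, start + c))
        start += c
    return cols


def _linear_predictor(params: ModelParams, data: StudyData) -> np.ndarray:
    idx = compute_indices(data.quantiles, data.groups, params.weights)
    eta = params.beta0 + idx @ params.betas
    if data.Z is not None and params.phi is not None:
        eta = eta + data.Z @ params.phi
    return eta


def log_likelihood(params: ModelParams, data: StudyData) -> float:
    """Bernoulli-logit log likelihood, stabilized via log(1+e^eta) = logaddexp."""
    eta = _linear_predictor(params, data)
    return float(np.sum(data.y * eta) - np.sum(np.logaddexp(0.0, eta)))


def _dirichlet_logpdf(w: np.ndarray, alpha: np.ndarray) -> float:
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
        return -np.inf
    interior_needed = np.any(alpha < 1.0)
    wc = np.clip(w, 1e-300 if not interior_needed else 0.0, None)
    if np.any(wc == 0.0):
        return -np.inf
    return float(
        gammaln(alpha.sum()) - gammaln(alpha).sum()
        + np.sum((alpha - 1.0) * np.log(wc))
    )


def _normal_logpdf(x: np.ndarray | float, sd: float) -> float:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    return float(-0.5 * np.sum((x / sd) ** 2)
                 - x.size * (0.5 * np.log(2 * np.pi) + np.log(sd)))


def log_prior(params: ModelParams, priors: PriorSpec,
              groups: GroupStructure,
              sigmas: np.ndarray | None = None) -> float:
    """Log prior density at ``params``.

    Weights outside a simplex yield -inf (a rejected state, not an error).
    Under the hierarchical variant, ``sigmas`` holds the sampled prior sds for
    (beta0, betas, phi) jointly and a flat Uniform(0, sigma_upper) prior term
    for each is included; otherwise fixed sds from the spec are used.
    """
    if not params.weights_valid():
        return -np.inf
    alphas = priors.alphas_for(groups)
    lp = 0.0
    for w, a in zip(params.weights, alphas):
        d = _dirichlet_logpdf(w, a)
        if not np.isfinite(d):
            return -np.inf
        lp += d

    p = 0 if params.phi is None else params.phi.size
    coef = np.concatenate([[params.beta0], params.betas,
                           params.phi if p else []])
    if priors.hierarchical_sigma:
        if sigmas is None:
            raise ValueError("hierarchical prior requires sampled sigmas")
        sigmas = np.atleast_1d(np.asarray(sigmas, dtype=float))
        if sigmas.shape != coef.shape:
            raise ValueError("one sigma required per coefficient")
        if np.any(sigmas <= 0) or np.any(sigmas > priors.sigma_upper):
            return -np.inf
        start = 1 if priors.flat_intercept else 0
        for c, s in zip(coef[start:], sigmas[start:]):
            lp += _normal_logpdf(c, s)
        lp += -coef.size * np.log(priors.sigma_upper)  # Uniform(0, upper)
    else:
        if not priors.flat_intercept:
            lp += _normal_logpdf(params.beta0, priors.beta_prior_sd)
        lp += _normal_logpdf(params.betas, priors.beta_prior_sd)
        if p:
            lp += _normal_logpdf(params.phi, priors.phi_prior_sd)
    return lp


def log_posterior(params: ModelParams, data: StudyData, priors: PriorSpec,
                  sigmas: np.ndarray | None = None) -> float:
    """Unnormalized log posterior = log likelihood + log prior."""
    lp = log_prior(params, priors, data.groups, sigmas=sigmas)
    if not np.isfinite(lp):
        return -np.inf
    return lp + log_likelihood(params, data)


class BayesianGroupIndex:
    """Bayesian group index regression model for a binary outcome.

    Parameters
    ----------
    endog : array-like of 0/1
        Binary outcome per subject.
    quantiles : QuantileMatrix
        Integer quantile scores, subjects x chemicals.
    groups : GroupStructure
        Assignment of chemicals to exposure groups.
    exog : array-like, optional
        Covariate matrix (already encoded numerically; categorical covariates
        should be dummy-coded against a reference level).
    priors : PriorSpec, optional

    Examples
    --------
    >>> model = BayesianGroupIndex.from_dataframe(
    ...     df, group_map={"pcb138": "PCBs", "pcb153": "PCBs", ...},
    ...     outcome="case")
    >>> res = model.fit(n_iter=15000, n_burnin=5000, seed=7)
    >>> print(res.summary())
    """

    def __init__(self, endog, quantiles: QuantileMatrix,
                 groups: GroupStructure, exog=None,
                 covariate_names: list[str] | None = None,
                 priors: PriorSpec | None = None):
        exog_arr = None if exog is None else np.asarray(exog, dtype=float)
        if exog_arr is not None and exog_arr.ndim == 1:
            exog_arr = exog_arr[:, None]
        if covariate_names is None and exog_arr is not None:
            covariate_names = [f"z{j}" for j in range(exog_arr.shape[1])]
        self.data = StudyData(np.asarray(endog), quantiles, groups,
                              Z=exog_arr, covariate_names=covariate_names)
        self.priors = priors if priors is not None else PriorSpec()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group_map: dict[str, str],
                       outcome: str, covariates: list[str] | None = None,
                       Q: int = 4, group_order: list[str] | None = None,
                       priors: PriorSpec | None = None,
                       lod: dict[str, float] | None = None,
                       lod_seed: int = 0) -> "BayesianGroupIndex":
        """Build the model from a tidy dataframe.

        Chemical columns are those named in ``group_map``; they are imputed
        below the LOD (if ``lod`` given) and converted to quantile scores.
        Rows with missing covariate or outcome values are dropped
        (complete-case analysis). Categorical covariates are dummy-coded
        against their first level.
        """
        chem_cols = list(group_map)
        needed = chem_cols + [outcome] + (covariates or [])
        sub = df[needed].dropna(axis=0)
        table = ExposureTable.from_dataframe(sub[chem_cols], lod=lod)
        if lod is not None:
            table = table.impute(lod_seed)
        quantiles = quantize_exposures(table, Q=Q)
        groups = build_group_structure(group_map, group_order=group_order)
        exog = None
        cov_names: list[str] | None = None
        if covariates:
            Zdf = pd.get_dummies(sub[covariates], drop_first=True, dtype=float)
            exog = Zdf.to_numpy()
            cov_names = list(Zdf.columns)
        return cls(sub[outcome].to_numpy(), quantiles, groups, exog=exog,
                   covariate_names=cov_names, priors=priors)

    @property
    def n_subjects(self) -> int:
        return self.data.n_subjects

    @property
    def n_groups(self) -> int:
        return self.data.groups.n_groups

    def log_posterior(self, params: ModelParams,
                      sigmas: np.ndarray | None = None) -> float:
        return log_posterior(params, self.data, self.priors, sigmas=sigmas)

    def fit(self, n_iter: int = 15000, n_burnin: int = 5000,
            n_chains: int = 2, seed: int = 0, target_accept: float = 0.35,
            prior_only: bool = False):
        """Draw from the posterior by Metropolis-within-Gibbs.

        Returns a :class:`~bgindex.results.BayesianGroupIndexResults`. Two
        chains from overdispersed starts are run by default so the
        Gelman-Rubin diagnostic is available; ``prior_only=True`` switches the
        likelihood off (useful for prior-recovery checks).
        """
        from .sampler import SamplerConfig, sample_posterior
        from .results import BayesianGroupIndexResults

        config = SamplerConfig(n_iter=n_iter, n_burnin=n_burnin,
                               n_chains=n_chains, seed=seed,
                               target_accept=target_accept)
        draws = sample_posterior(self.data, self.priors, config,
                                 prior_only=prior_only)
        return BayesianGroupIndexResults(self, draws)
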