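"""Two-step grouped weighted quantile sum (GWQS) regression.

The frequentist comparator: (1) split the data into training and validation
parts, stratified on the outcome; (2) on bootstrap resamples of the training
part, maximize the logistic likelihood in (beta0, beta_k, w_k, phi) subject
to each group's weights lying on the probability simplex, and aggregate the
replicate weights into one weight vector per group (averaging weighted by the
significance |z| of the replicate's index effect, the usual WQS convention);
(3) on the validation part, fit an ordinary logistic regression of the
outcome on the K indices constructed with those fixed weights and report
odds ratios with Wald 95% confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .data import StudyData
from .model import compute_indices, _default_columns

__all__ = ["GWQSConfig", "split_data", "estimate_weights_bootstrap",
           "fit_validation", "GroupWQS", "GWQSResults"]


@dataclass
class GWQSConfig:
    """Settings for the two-step GWQS fit.

    train_fraction=0.4 follows the original WQS convention (40% of subjects
    estimate the weights, 60% estimate the effects); n_bootstrap resamples
    are drawn from the training part; n_starts multistarts per resample guard
    against local optima of the constrained likelihood.
    """

    train_fraction: float = 0.4
    n_bootstrap: int = 100
    tol: float = 1e-8
    seed: int = 0
    n_starts: int = 3
    signal_weighted: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_bootstrap < 1:
            raise ValueError("need at least one bootstrap replicate")


def split_data(data: StudyData, config: GWQSConfig
               ) -> tuple[StudyData, StudyData]:
    """Disjoint, exhaustive train/validation split, stratified on the outcome.

    Deterministic given the config seed. Raises if either part would be
    missing an outcome class (only possible when a class has a single
    member).
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 71)))
    n = data.n_subjects
    train_idx: list[np.ndarray] = []
    for cls in (0, 1):
        members = np.flatnonzero(data.y == cls)
        if len(members) < 2:
            raise ValueError(
                f"outcome class {cls} has {len(members)} subjects; "
                "cannot place it in both the training and validation part")
        n_tr = int(round(config.train_fraction * len(members)))
        n_tr = min(max(n_tr, 1), len(members) - 1)
        perm = rng.permutation(members)
        train_idx.append(perm[:n_tr])
    tr = np.sort(np.concatenate(train_idx))
    va = np.setdiff1d(np.arange(n), tr)
    return data.subset(tr), data.subset(va)


def _group_columns(data: StudyData) -> list[np.ndarray]:
    ids = data.quantiles.chemical_ids
    if ids is None:
        return _default_columns(data.groups)
    return data.groups.member_indices(ids)


def _constrained_mle(y: np.ndarray, Qg: list[np.ndarray],
                     Z: np.ndarray | None, config: GWQSConfig,
                     rng: np.random.Generator
                     ) -> tuple[list[np.ndarray], np.ndarray] | None:
    """Maximize the logistic likelihood with simplex-constrained weights.

    Parameter vector: [beta0, beta_1..K, phi_1..p, w(group 1), ..., w(group K)]
    with bounds w in [0, 1] and one equality constraint per group
    (sum w = 1), solved by SLSQP with an analytic gradient. Returns
    (weights per group, betas) of the best of ``n_starts`` starts, or None
    when every start fails.
    """
    K = len(Qg)
    sizes = [qg.shape[1] for qg in Qg]
    p = 0 if Z is None else Z.shape[1]
    n_lin = 1 + K + p
    n_par = n_lin + sum(sizes)
    offs = np.cumsum([n_lin] + sizes)  # weight slice k: offs[k]:offs[k+1]

    def unpack(x):
        beta0, betas = x[0], x[1:1 + K]
        phi = x[1 + K:n_lin]
        ws = [x[offs[k]:offs[k + 1]] for k in range(K)]
        return beta0, betas, phi, ws

    def eta_of(x):
        beta0, betas, phi, ws = unpack(x)
        eta = np.full(len(y), beta0)
        for k in range(K):
            eta += betas[k] * (Qg[k] @ ws[k])
        if p:
            eta += Z @ phi
        return eta, betas, ws

    def negll(x):
        eta, _, _ = eta_of(x)
        return -(y @ eta - np.logaddexp(0.0, eta).sum())

    def grad(x):
        eta, betas, ws = eta_of(x)
        r = 1.0 / (1.0 + np.exp(-eta)) - y  # d(-ll)/d(eta)
        g = np.empty(n_par)
        g[0] = r.sum()
        for k in range(K):
            idxk = Qg[k] @ ws[k]
            g[1 + k] = r @ idxk
            g[offs[k]:offs[k + 1]] = betas[k] * (Qg[k].T @ r)
        if p:
            g[1 + K:n_lin] = Z.T @ r
        return g

    def _simplex_constraint(lo: int, hi: int) -> dict:
        jvec = np.zeros(n_par)
        jvec[lo:hi] = 1.0
        return {"type": "eq",
                "fun": lambda x: x[lo:hi].sum() - 1.0,
                "jac": lambda x: jvec}

    constraints = [_simplex_constraint(offs[k], offs[k + 1])
                   for k in range(K)]
    bounds = ([(None, None)] * n_lin) + [(0.0, 1.0)] * sum(sizes)

    best = None
    for s in range(config.n_starts):
        x0 = np.zeros(n_par)
        if s == 0:
            for k in range(K):
                x0[offs[k]:offs[k + 1]] = 1.0 / sizes[k]
        else:
            x0[:n_lin] = 0.5 * rng.standard_normal(n_lin)
            for k in range(K):
                x0[offs[k]:offs[k + 1]] = rng.dirichlet(np.ones(sizes[k]))
        res = optimize.minimize(
            negll, x0, jac=grad, method="SLSQP", bounds=bounds,
            constraints=constraints,
            options={"ftol": config.tol, "maxiter": 200},
        )
        if not res.success:
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        return None
    _, betas, _, ws = unpack(best.x)
    ws = [np.clip(w, 0.0, None) for w in ws]
    ws = [w / w.sum() for w in ws]
    return ws, betas.copy()


def estimate_weights_bootstrap(train: StudyData, config: GWQSConfig
                               ) -> list[np.ndarray]:
    """Bootstrap estimate of the K weight simplices from the training part.

    Each resample is fitted by constrained maximum likelihood; the final
    weight vector per group is the replicate average, weighted by the |z|
    statistic of that replicate's index effect (an unconstrained logistic
    refit on the replicate's constructed indices) when
    ``config.signal_weighted``, or unweighted otherwise. Failed replicates
    are dropped with a warning; if all fail, an error is raised.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 72)))
    cols = _group_columns(train)
    qf = train.quantiles.q.astype(float)
    n = train.n_subjects
    K = train.groups.n_groups
    sizes = train.groups.sizes

    w_reps: list[list[np.ndarray]] = [[] for _ in range(K)]
    z_reps: list[list[float]] = [[] for _ in range(K)]
    n_failed = 0
    for _ in range(config.n_bootstrap):
        rows = rng.integers(0, n, size=n)
        y_b = train.y[rows]
        if y_b.min() == y_b.max():
            n_failed += 1
            continue
        Qg = [qf[np.ix_(rows, c)] for c in cols]
        Z_b = None if train.Z is None else train.Z[rows]
        fit = _constrained_mle(y_b, Qg, Z_b, config, rng)
        if fit is None:
            n_failed += 1
            continue
        ws, _ = fit
        zstats = _index_zstats(y_b, Qg, Z_b, ws)
        for k in range(K):
            w_reps[k].append(ws[k])
            z_reps[k].append(zstats[k])
    if not w_reps[0]:
        raise RuntimeError("every bootstrap replicate failed to fit")
    if n_failed:
        warnings.warn(f"{n_failed} of {config.n_bootstrap} bootstrap "
                      "replicates failed and were dropped")

    out = []
    for k in range(K):
        W = np.vstack(w_reps[k])
        if config.signal_weighted:
            z = np.abs(np.asarray(z_reps[k]))
            if z.sum() <= 0:
                z = np.ones(len(z))
            w = z @ W / z.sum()
        else:
            w = W.mean(axis=0)
        w = np.clip(w, 0.0, None)
        out.append(w / w.sum())
        assert abs(out[k].sum() - 1.0) < 1e-9 and out[k].shape == (sizes[k],)
    return out


def _index_zstats(y, Qg, Z, ws) -> np.ndarray:
    """|z| of each index effect from an unconstrained logistic refit."""
    idx = np.column_stack([qg @ w for qg, w in zip(Qg, ws)])
    X = sm.add_constant(idx if Z is None else np.column_stack([idx, Z]),
                        has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        z = fit.params[1:1 + idx.shape[1]] / fit.bse[1:1 + idx.shape[1]]
        z = np.nan_to_num(z, nan=0.0, posinf=0.0, neginf=0.0)
    except Exception:
        z = np.zeros(idx.shape[1])
    return np.abs(z)


def fit_validation(weights: list[np.ndarray], validation: StudyData
                   ) -> pd.DataFrame:
    """Logistic fit of the outcome on the fixed-weight indices (+ covariates).

    Returns one row per group and covariate with the OR, Wald 95% CI and a
    separation flag; separation yields infinite interval bounds rather than
    an exception. A constant index raises, since its effect is inestimable.
    """
    idx = compute_indices(validation.quantiles, validation.groups, weights)
    K = idx.shape[1]
    for k in range(K):
        if np.ptp(idx[:, k]) == 0:
            raise ValueError(
                f"index {validation.groups.group_names[k]!r} is constant on "
                "the validation part; its effect is inestimable")
    X = idx if validation.Z is None else np.column_stack(
        [idx, validation.Z])
    X = sm.add_constant(X, has_constant="add")
    names = (list(validation.groups.group_names)
             + list(validation.covariate_names or []))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(validation.y, X).fit(disp=0, maxiter=200)
    params = fit.params[1:]
    bse = fit.bse[1:]
    rows = []
    for j, nm in enumerate(names):
        se = bse[j]
        separated = not np.isfinite(se) or se > 50.0
        lo = params[j] - 1.959963984540054 * se
        hi = params[j] + 1.959963984540054 * se
        rows.append({
            "variable": nm,
            "kind": "group" if j < K else "covariate",
            "odds_ratio": float(np.exp(params[j])),
            "ci_lower": 0.0 if separated else float(np.exp(lo)),
            "ci_upper": np.inf if separated else float(np.exp(hi)),
            "separation": bool(separated),
        })
    df = pd.DataFrame(rows)
    df["significant"] = (df["ci_lower"] > 1.0) | (df["ci_upper"] < 1.0)
    return df


@dataclass
class GWQSResults:
    """Two-step GWQS fit output."""

    effects: pd.DataFrame
    weights: pd.DataFrame
    estimated_weights: list[np.ndarray]
    config: GWQSConfig

    def or_interval(self, k: int) -> tuple[float, float, float]:
        row = self.effects.iloc[k]
        return row["odds_ratio"], row["ci_lower"], row["ci_upper"]

    def summary(self) -> str:
        lines = ["Grouped WQS regression (two-step)", "=" * 60,
                 "Odds ratios (validation fit, Wald 95% CI)", "-" * 60]
        for _, r in self.effects.iterrows():
            flag = "*" if r["significant"] else " "
            lines.append(f"  {r['variable']:<24s} {r['odds_ratio']:7.3f}  "
                         f"({r['ci_lower']:6.3f}, {r['ci_upper']:6.3f}) {flag}")
        return "\n".join(lines)


class GroupWQS:
    """Two-step grouped WQS model (frequentist comparator).

    Same data surface as :class:`~bgindex.model.BayesianGroupIndex`; ``fit``
    performs the split / bootstrap-weights / validation-fit pipeline.
    """

    def __init__(self, endog, quantiles, groups, exog=None,
                 covariate_names=None):
        exog_arr = None if exog is None else np.asarray(exog, dtype=float)
        if exog_arr is not None and exog_arr.ndim == 1:
            exog_arr = exog_arr[:, None]
        self.data = StudyData(np.asarray(endog), quantiles, groups,
                              Z=exog_arr, covariate_names=covariate_names)

    def fit(self, config: GWQSConfig | None = None, **kwargs) -> GWQSResults:
        if config is None:
            config = GWQSConfig(**kwargs)
        train, valid = split_data(self.data, config)
        ws = estimate_weights_bootstrap(train, config)
        effects = fit_validation(ws, valid)
        groups = self.data.groups
        wrows = []
        for k, g in enumerate(groups.group_names):
            for chem, w in zip(groups.chemicals_in(k), ws[k]):
                wrows.append({"chemical": chem, "group": g,
                              "weight": float(w),
                              "threshold": float(groups.thresholds[k])})
        wdf = pd.DataFrame(wrows)
        wdf["important"] = wdf["weight"] >= wdf["threshold"]
        return GWQSResults(effects=effects, weights=wdf,
                           estimated_weights=ws, config=config)
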