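"""Simulation study: scenario definitions, data generation, and metrics.

The study emulates a case-control design with blocks of correlated chemical
exposures. Four scenario sets vary the group structure:

====  =========  ===========  =====================  ====
set   chemicals  group sizes  important per group    n
====  =========  ===========  =====================  ====
A     9          (5, 4)       (2, 2)                 1000
B     14         (5, 4, 5)    (1, 1, 1)              1000
C     14         (5, 4, 5)    (3, 2, 3)              1000
D     14         (5, 4, 5)    (3, 2, 3)              500
====  =========  ===========  =====================  ====

Five strength levels set the true odds ratios per group (level 1 is the null,
OR = 1 everywhere; the first group's association is negative, the rest
positive): sets A-C use OR 1.50/2.00/2.50/3.00 with reciprocals
0.67/0.50/0.40/0.33, set D the smaller 1.25/1.50/1.75/2.00 with reciprocals
0.80/0.67/0.57/0.50. Correlation structures: weak (0.5 within group, 0.1
across), moderate (0.7, 0.3), strong (0.9, 0.5).

Exposures are multivariate normal with the block correlation structure and
standard-normal marginals (quantization erases location and scale anyway).
Within each replicate dataset quartile scores are computed from that dataset,
the true index is formed from the scenario's true weights (important
chemicals share the group weight equally; unimportant ones have weight
exactly 0), and the binary outcome is drawn from the logistic model
p = 1/(1+exp(-eta)), eta = beta0* + sum_k beta_k* WQS_k*. The intercept is
calibrated as beta0* = -sum_k beta_k* E[WQS_k*] (E = (Q-1)/2 per index) so
the expected case fraction is near one half; a dataset is accepted only when
its case fraction lies in the 50 +/- 10% band, otherwise the outcome is
redrawn.

Evaluation across replicates: power/type-I error (proportion of 95%
intervals excluding OR = 1), bias and MSE of the estimated ORs (on the OR
scale by default), and sensitivity/specificity of chemical importance calls
at the 1/C_k threshold, pooled over chemicals and replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (GroupStructure, QuantileMatrix, StudyData,
                   build_group_structure, quantize_exposures, ExposureTable)
from .model import BayesianGroupIndex, PriorSpec, compute_indices
from .gwqs import GroupWQS, GWQSConfig

__all__ = [
    "CorrelationSpec", "CORRELATIONS", "SimulationScenario",
    "build_scenario", "generate_exposures", "generate_outcome",
    "generate_dataset", "run_replicates", "ReplicateResults",
    "compute_power", "compute_bias_mse", "compute_sensitivity_specificity",
]

_GROUP_SIZES = {"A": (5, 4), "B": (5, 4, 5), "C": (5, 4, 5), "D": (5, 4, 5)}
_N_IMPORTANT = {"A": (2, 2), "B": (1, 1, 1), "C": (3, 2, 3), "D": (3, 2, 3)}
_DEFAULT_N = {"A": 1000, "B": 1000, "C": 1000, "D": 500}
# positive-direction OR at strength levels 1..5; the first group gets the
# reciprocal (negative association), the remaining groups the value itself
_POSITIVE_OR = {
    "A": (1.0, 1.5, 2.0, 2.5, 3.0),
    "B": (1.0, 1.5, 2.0, 2.5, 3.0),
    "C": (1.0, 1.5, 2.0, 2.5, 3.0),
    "D": (1.0, 1.25, 1.5, 1.75, 2.0),
}

#: accepted case-fraction band (50 +/- 10% cases)
CASE_FRACTION_BAND = (0.40, 0.60)


@dataclass(frozen=True)
class CorrelationSpec:
    """Exchangeable block correlation: ``within`` inside each chemical group,
    ``across`` between groups."""

    within: float
    across: float

    def matrix(self, block_sizes) -> np.ndarray:
        sizes = np.asarray(block_sizes, dtype=int)
        c = int(sizes.sum())
        labels = np.repeat(np.arange(len(sizes)), sizes)
        same = labels[:, None] == labels[None, :]
        R = np.where(same, self.within, self.across)
        np.fill_diagonal(R, 1.0)
        try:
            np.linalg.cholesky(R)
        except np.linalg.LinAlgError:
            raise ValueError(
                f"correlation (within={self.within}, across={self.across}) "
                f"with blocks {list(sizes)} is not positive definite"
            ) from None
        return R


CORRELATIONS = {
    "weak": CorrelationSpec(0.5, 0.1),
    "moderate": CorrelationSpec(0.7, 0.3),
    "strong": CorrelationSpec(0.9, 0.5),
}


@dataclass
class SimulationScenario:
    """Generative truth for one simulation condition."""

    scenario_set: str
    strength_level: int
    correlation: str
    n: int
    group_sizes: tuple[int, ...]
    true_ors: np.ndarray
    true_weights: list[np.ndarray]
    Q: int = 4
    groups: GroupStructure = field(init=False)
    chemical_ids: list[str] = field(init=False)

    def __post_init__(self) -> None:
        assignment = {}
        names = [f"g{k + 1}" for k in range(len(self.group_sizes))]
        self.chemical_ids = []
        for k, c in enumerate(self.group_sizes):
            for j in range(c):
                chem = f"x{k + 1}_{j + 1}"
                assignment[chem] = names[k]
                self.chemical_ids.append(chem)
        self.groups = build_group_structure(assignment, group_order=names)

    @property
    def true_betas(self) -> np.ndarray:
        return np.log(self.true_ors)

    @property
    def true_beta0(self) -> float:
        # center the linear predictor: E[WQS_k*] = (Q-1)/2 for simplex weights
        return float(-(self.Q - 1) / 2.0 * self.true_betas.sum())

    @property
    def correlation_spec(self) -> CorrelationSpec:
        return CORRELATIONS[self.correlation]

    def important_mask(self) -> np.ndarray:
        """Boolean per chemical (scenario column order): true weight > 0."""
        return np.concatenate(
            [w > 0 for w in self.true_weights])


def build_scenario(scenario_set: str, strength: int, correlation: str,
                   n: int | None = None, Q: int = 4) -> SimulationScenario:
    """Assemble the generative truth for one (set, strength, correlation) cell.

    Important chemicals are the leading ones of each group and share the
    group's weight equally; the rest have true weight exactly 0. At strength
    level 1 all ORs are 1 (the null); above that the first group's OR is the
    reciprocal of the level's positive OR and the other groups take the
    positive OR itself.
    """
    scenario_set = scenario_set.upper()
    if scenario_set not in _GROUP_SIZES:
        raise ValueError(f"unknown scenario set {scenario_set!r}")
    if strength not in (1, 2, 3, 4, 5):
        raise ValueError("strength level must be 1..5")
    if correlation not in CORRELATIONS:
        raise ValueError(f"unknown correlation {correlation!r}; "
                         f"choose from {sorted(CORRELATIONS)}")
    sizes = _GROUP_SIZES[scenario_set]
    n_imp = _N_IMPORTANT[scenario_set]
    pos_or = _POSITIVE_OR[scenario_set][strength - 1]
    ors = np.array([1.0 / pos_or] + [pos_or] * (len(sizes) - 1))
    weights = []
    for c, m in zip(sizes, n_imp):
        w = np.zeros(c)
        w[:m] = 1.0 / m
        weights.append(w)
    return SimulationScenario(
        scenario_set=scenario_set, strength_level=strength,
        correlation=correlation,
        n=_DEFAULT_N[scenario_set] if n is None else n,
        group_sizes=sizes, true_ors=ors, true_weights=weights, Q=Q,
    )


def generate_exposures(scenario: SimulationScenario,
                       seed: int | np.random.Generator) -> ExposureTable:
    """Draw n x C multivariate-normal exposures with the scenario's block
    correlation and standard-normal marginals."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    R = scenario.correlation_spec.matrix(scenario.group_sizes)
    L = np.linalg.cholesky(R)
    X = rng.standard_normal((scenario.n, R.shape[0])) @ L.T
    return ExposureTable(X, list(scenario.chemical_ids))


def generate_outcome(scenario: SimulationScenario, q: QuantileMatrix,
                     seed: int | np.random.Generator,
                     max_retries: int = 200) -> tuple[np.ndarray, int]:
    """Draw the binary outcome from the true logistic model.

    The draw is accepted only when the case fraction lands in the 50 +/- 10%
    band; otherwise the outcome is redrawn with fresh randomness, up to
    ``max_retries`` times (exhaustion signals a miscalibrated intercept and
    raises). Returns (y, number of attempts used).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    idx = compute_indices(q, scenario.groups, scenario.true_weights)
    eta = scenario.true_beta0 + idx @ scenario.true_betas
    p = 1.0 / (1.0 + np.exp(-eta))
    lo, hi = CASE_FRACTION_BAND
    for attempt in range(1, max_retries + 1):
        y = (rng.random(scenario.n) < p).astype(float)
        if lo <= y.mean() <= hi:
            return y, attempt
    raise RuntimeError(
        f"case fraction left the {lo:.0%}-{hi:.0%} band in {max_retries} "
        "consecutive draws; the true intercept looks miscalibrated")


def generate_dataset(scenario: SimulationScenario,
                     seed: int | np.random.Generator) -> StudyData:
    """One replicate dataset: exposures -> within-dataset quartiles -> outcome."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    table = generate_exposures(scenario, rng)
    q = quantize_exposures(table, Q=scenario.Q)
    y, _ = generate_outcome(scenario, q, rng)
    return StudyData(y, q, scenario.groups)


@dataclass
class ReplicateResults:
    """Tidy per-replicate outputs of :func:`run_replicates`.

    effects: one row per (replicate, method, group) with the estimated OR and
    95% interval; weights: one row per (replicate, method, chemical) with the
    estimated and true weight; failures: replicates that failed to fit.
    """

    effects: pd.DataFrame
    weights: pd.DataFrame
    failures: pd.DataFrame
    scenario: SimulationScenario


def run_replicates(scenario: SimulationScenario, n_reps: int = 25,
                   methods: tuple[str, ...] = ("bayes", "gwqs"),
                   seed: int = 0,
                   n_iter: int = 15000, n_burnin: int = 5000,
                   n_chains: int = 2,
                   priors: PriorSpec | None = None,
                   gwqs_config: GWQSConfig | None = None,
                   progress: bool = False) -> ReplicateResults:
    """Generate ``n_reps`` replicate datasets and fit each requested method.

    Replicates use independent spawned seeds from the master seed, so a rerun
    with the same seed reproduces every number; fit failures are recorded in
    ``failures`` rather than silently dropped. MCMC settings default to
    15,000 iterations / 5,000 burn-in: with this sampler's autocorrelation,
    roughly 10,000 retained draws per chain are needed for the Gelman-Rubin
    upper bound to clear the 1.10 convergence criterion reliably; shorter
    chains are fine for exploratory runs that tolerate convergence flags.
    """
    unknown = set(methods) - {"bayes", "gwqs"}
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    eff_rows, w_rows, fail_rows = [], [], []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_reps)
    true_w = np.concatenate(scenario.true_weights)
    thresholds = np.concatenate([
        np.full(c, 1.0 / c) for c in scenario.group_sizes])
    group_names = scenario.groups.group_names

    for rep, child in enumerate(children):
        rep_seed = int(child.generate_state(1, np.uint64)[0] >> 33)
        data = generate_dataset(scenario, np.random.default_rng(child))
        for method in methods:
            try:
                if method == "bayes":
                    model = BayesianGroupIndex(
                        data.y, data.quantiles, data.groups, priors=priors)
                    res = model.fit(n_iter=n_iter, n_burnin=n_burnin,
                                    n_chains=n_chains, seed=rep_seed)
                    eff = res.effects
                    wdf = res.weights
                    converged = res.converged
                    max_upper = res.max_psrf_upper
                else:
                    cfg = gwqs_config or GWQSConfig()
                    cfg = GWQSConfig(
                        train_fraction=cfg.train_fraction,
                        n_bootstrap=cfg.n_bootstrap, tol=cfg.tol,
                        seed=rep_seed, n_starts=cfg.n_starts,
                        signal_weighted=cfg.signal_weighted)
                    res = GroupWQS(data.y, data.quantiles,
                                   data.groups).fit(cfg)
                    eff = res.effects
                    wdf = res.weights
                    converged = True
                    max_upper = np.nan
            except Exception as exc:  # recorded, not dropped
                fail_rows.append({"replicate": rep, "method": method,
                                  "reason": f"{type(exc).__name__}: {exc}"})
                continue
            for k, g in enumerate(group_names):
                row = eff.iloc[k]
                eff_rows.append({
                    "replicate": rep, "method": method, "group": g,
                    "true_or": scenario.true_ors[k],
                    "est_or": row["odds_ratio"],
                    "ci_lower": row["ci_lower"],
                    "ci_upper": row["ci_upper"],
                    "converged": converged, "max_psrf_upper": max_upper,
                })
            est_w = wdf.set_index("chemical").loc[
                scenario.chemical_ids, "weight"].to_numpy()
            for chem, w_hat, w_true, thr in zip(
                    scenario.chemical_ids, est_w, true_w, thresholds):
                w_rows.append({
                    "replicate": rep, "method": method, "chemical": chem,
                    "group": scenario.groups.group_names[
                        scenario.groups.assignment[chem]],
                    "weight": w_hat, "true_weight": w_true,
                    "threshold": thr, "truly_important": w_true > 0,
                })
        if progress:  # pragma: no cover
            print(f"replicate {rep + 1}/{n_reps} done", flush=True)

    return ReplicateResults(
        effects=pd.DataFrame(eff_rows), weights=pd.DataFrame(w_rows),
        failures=pd.DataFrame(fail_rows,
                              columns=["replicate", "method", "reason"]),
        scenario=scenario)


def compute_power(results: ReplicateResults | pd.DataFrame,
                  null_value: float = 1.0) -> pd.DataFrame:
    """Proportion of replicate 95% intervals excluding ``null_value``.

    Under a null scenario this is the type-I error. One row per
    (method, group), with the replicate count.
    """
    eff = results.effects if isinstance(results, ReplicateResults) else results
    if eff.empty:
        raise ValueError("no successful replicates")
    excl = (eff["ci_lower"] > null_value) | (eff["ci_upper"] < null_value)
    out = (eff.assign(excludes=excl)
           .groupby(["method", "group"], sort=False)
           .agg(power=("excludes", "mean"), n_replicates=("excludes", "size"))
           .reset_index())
    return out


def compute_bias_mse(results: ReplicateResults | pd.DataFrame,
                     scale: str = "or") -> pd.DataFrame:
    """Bias and MSE of the estimated group effects across replicates.

    On the OR scale (default): bias = mean(est OR) - true OR and
    MSE = mean((est OR - true OR)^2); ``scale='log'`` computes both on the
    log-OR scale instead.
    """
    eff = results.effects if isinstance(results, ReplicateResults) else results
    if eff.empty:
        raise ValueError("no successful replicates")
    if scale not in ("or", "log"):
        raise ValueError("scale must be 'or' or 'log'")
    est = eff["est_or"] if scale == "or" else np.log(eff["est_or"])
    tru = eff["true_or"] if scale == "or" else np.log(eff["true_or"])
    err = est - tru
    out = (eff.assign(_err=err, _sq=err ** 2, _est=est)
           .groupby(["method", "group"], sort=False)
           .agg(mean_est=("_est", "mean"), bias=("_err", "mean"),
                mse=("_sq", "mean"), n_replicates=("_err", "size"))
           .reset_index())
    return out


def compute_sensitivity_specificity(results: ReplicateResults | pd.DataFrame
                                    ) -> pd.DataFrame:
    """Importance-call sensitivity and specificity, pooled over chemicals and
    replicates.

    sensitivity = P(estimated weight >= 1/C_k | truly important);
    specificity = P(estimated weight < 1/C_k | truly unimportant). The
    threshold comparison is boundary-inclusive on the important side.
    """
    wdf = results.weights if isinstance(results, ReplicateResults) else results
    if wdf.empty:
        raise ValueError("no successful replicates")
    called = wdf["weight"] >= wdf["threshold"]
    rows = []
    for method, sub in wdf.assign(called=called).groupby("method", sort=False):
        imp = sub[sub["truly_important"]]
        unimp = sub[~sub["truly_important"]]
        rows.append({
            "method": method,
            "sensitivity": float(imp["called"].mean()) if len(imp) else np.nan,
            "specificity": (float((~unimp["called"]).mean())
                            if len(unimp) else np.nan),
            "n_important": len(imp), "n_unimportant": len(unimp),
        })
    return pd.DataFrame(rows)
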