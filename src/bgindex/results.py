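"""Posterior summaries: odds-ratio tables, weight estimates, plot data.

Effects are reported as posterior mean odds ratios with equal-tailed 95%
credible intervals (the 2.5% and 97.5% posterior quantiles); a group effect
is called significant when its interval excludes 1.00. A chemical is called
important when its posterior mean weight meets or exceeds the equal-share
threshold 1/C_k of its group (boundary inclusive).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import GroupStructure
from .sampler import PosteriorDraws

__all__ = [
    "summarize_effects",
    "summarize_weights",
    "classify_important",
    "forest_plot_data",
    "weight_plot_data",
    "BayesianGroupIndexResults",
]


def _or_row(name: str, kind: str, draws_1d: np.ndarray) -> dict:
    ors = np.exp(draws_1d)
    lo, hi = np.quantile(ors, [0.025, 0.975])
    return {
        "variable": name, "kind": kind,
        "odds_ratio": float(ors.mean()),
        "ci_lower": float(lo), "ci_upper": float(hi),
        "significant": bool(lo > 1.0 or hi < 1.0),
    }


def summarize_effects(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean OR and equal-tailed 95% credible interval per effect.

    One row per exposure group and per covariate, columns
    (variable, kind, odds_ratio, ci_lower, ci_upper, significant).
    """
    rows = []
    for k, g in enumerate(draws.groups.group_names):
        rows.append(_or_row(g, "group", draws.betas[:, :, k].ravel()))
    if draws.phi is not None:
        names = draws.covariate_names or [
            f"z{j}" for j in range(draws.phi.shape[2])]
        for j, nm in enumerate(names):
            rows.append(_or_row(nm, "covariate", draws.phi[:, :, j].ravel()))
    return pd.DataFrame(rows)


def summarize_weights(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean weight per chemical, with its group and 1/C_k threshold."""
    groups = draws.groups
    rows = []
    for k, g in enumerate(groups.group_names):
        means = draws.weights[k].reshape(-1, groups.sizes[k]).mean(axis=0)
        for chem, w in zip(groups.chemicals_in(k), means):
            rows.append({"chemical": chem, "group": g,
                         "weight": float(w),
                         "threshold": float(groups.thresholds[k])})
    df = pd.DataFrame(rows)
    df["important"] = df["weight"] >= df["threshold"]
    return df


def classify_important(weights: pd.DataFrame,
                       groups: GroupStructure | None = None) -> pd.Series:
    """Importance flag per chemical: mean weight >= 1/C_k (boundary inclusive).

    ``weights`` is a frame like :func:`summarize_weights` output; ``groups``
    may supply thresholds if the frame lacks a ``threshold`` column.
    """
    if "threshold" in weights.columns:
        thr = weights["threshold"]
    else:
        if groups is None:
            raise ValueError("need a threshold column or a GroupStructure")
        name_to_k = {g: k for k, g in enumerate(groups.group_names)}
        thr = weights["group"].map(
            lambda g: groups.thresholds[name_to_k[g]])
    return (weights["weight"] >= thr).rename("important")


def forest_plot_data(effects: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready forest table: input order preserved, null line at 1.0."""
    out = effects[["variable", "kind", "odds_ratio",
                   "ci_lower", "ci_upper"]].copy()
    out["null_value"] = 1.0
    return out.reset_index(drop=True)


def weight_plot_data(weights: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready weight-bar table grouped by index, thresholds attached."""
    cols = ["group", "chemical", "weight", "threshold"]
    return weights[cols].sort_values(
        "group", kind="stable").reset_index(drop=True)


class BayesianGroupIndexResults:
    """Fit results: posterior draws plus the tables derived from them.

    Attributes
    ----------
    draws : PosteriorDraws
    effects : DataFrame — OR summary per group / covariate.
    weights : DataFrame — posterior mean weight per chemical.
    """

    def __init__(self, model, draws: PosteriorDraws):
        self.model = model
        self.draws = draws
        self._effects: pd.DataFrame | None = None
        self._weights: pd.DataFrame | None = None
        self._psrf: pd.DataFrame | None = None

    @property
    def effects(self) -> pd.DataFrame:
        if self._effects is None:
            self._effects = summarize_effects(self.draws)
        return self._effects

    @property
    def weights(self) -> pd.DataFrame:
        if self._weights is None:
            self._weights = summarize_weights(self.draws)
        return self._weights

    @property
    def psrf(self) -> pd.DataFrame:
        """Gelman-Rubin table (computed lazily; needs >= 2 chains)."""
        if self._psrf is None:
            from .diagnostics import gelman_rubin
            self._psrf = gelman_rubin(self.draws)
        return self._psrf

    @property
    def converged(self) -> bool:
        """True when every PSRF upper bound is below 1.10."""
        return bool(self.psrf["converged"].all())

    @property
    def max_psrf_upper(self) -> float:
        return float(self.psrf["upper"].max())

    def geweke(self) -> pd.DataFrame:
        from .diagnostics import geweke_table
        return geweke_table(self.draws)

    def or_interval(self, k: int) -> tuple[float, float, float]:
        """(posterior mean OR, 2.5%, 97.5%) for group k."""
        row = self.effects.iloc[k]
        return row["odds_ratio"], row["ci_lower"], row["ci_upper"]

    def summary(self) -> str:
        """Human-readable fit summary in the style of regression packages."""
        d = self.draws
        lines = [
            "Bayesian group index regression (logit link)",
            "=" * 60,
            f"Subjects: {self.model.n_subjects}    "
            f"Groups: {d.n_groups}    "
            f"Chains: {d.n_chains}    Retained draws/chain: {d.n_retained}",
            f"Max PSRF upper bound: {self.max_psrf_upper:.4f} "
            f"({'converged' if self.converged else 'NOT CONVERGED'}, "
            "criterion < 1.10)",
            "",
            "Odds ratios (posterior mean, equal-tailed 95% credible interval)",
            "-" * 60,
        ]
        for _, r in self.effects.iterrows():
            flag = "*" if r["significant"] else " "
            lines.append(
                f"  {r['variable']:<24s} {r['odds_ratio']:7.3f}  "
                f"({r['ci_lower']:6.3f}, {r['ci_upper']:6.3f}) {flag}"
            )
        lines += ["", "Chemical weights (posterior mean; "
                      "'*' = at or above 1/C_k)", "-" * 60]
        for _, r in self.weights.iterrows():
            flag = "*" if r["important"] else " "
            lines.append(
                f"  {r['group']:<12s} {r['chemical']:<20s} "
                f"{r['weight']:6.3f} (threshold {r['threshold']:.3f}) {flag}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<BayesianGroupIndexResults: {self.draws.n_groups} groups, "
                f"{self.draws.n_chains}x{self.draws.n_retained} draws>")
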