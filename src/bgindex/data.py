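"""Exposure containers, quantile scoring, grouping, and below-LOD imputation.

Chemical mixture analyses work on quantile scores rather than raw
concentrations: each chemical's concentrations are ranked within the analysis
sample and binned into Q ordered categories (0..Q-1, quartiles by default).
This reduces the influence of outliers and puts chemicals measured on very
different concentration scales onto a common footing. Concentrations censored
below a limit of detection (LOD) are imputed from a lognormal distribution
fitted to the censored data, truncated to (0, LOD).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ExposureTable",
    "QuantileMatrix",
    "GroupStructure",
    "StudyData",
    "quantize_exposures",
    "impute_below_lod",
    "build_group_structure",
    "read_exposures",
    "read_group_map",
    "read_lod",
]

# Fraction of measurements that must be above the LOD for a chemical to be
# eligible for imputation rather than exclusion.
MIN_DETECT_FRACTION = 0.2


@dataclass
class ExposureTable:
    """Raw chemical concentrations for n subjects x C chemicals.

    Parameters
    ----------
    values : ndarray, shape (n, C)
        Concentrations; units are arbitrary and may differ per chemical.
    chemical_ids : list of str
        Column names, one per chemical.
    lod : ndarray or None
        Optional per-chemical limit of detection (must be positive).
    below_lod_mask : ndarray of bool or None
        Optional mask marking censored entries.
    """

    values: np.ndarray
    chemical_ids: list[str]
    lod: np.ndarray | None = None
    below_lod_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (subjects x chemicals) array")
        n, c = self.values.shape
        if n < 2:
            raise ValueError("need at least 2 subjects")
        if c < 1:
            raise ValueError("need at least 1 chemical")
        if len(self.chemical_ids) != c:
            raise ValueError(
                f"{len(self.chemical_ids)} chemical ids for {c} columns"
            )
        if self.lod is not None:
            self.lod = np.asarray(self.lod, dtype=float)
            if self.lod.shape != (c,):
                raise ValueError("lod must have one entry per chemical")
            if np.any(self.lod <= 0):
                raise ValueError("limits of detection must be positive")
        if self.below_lod_mask is not None:
            self.below_lod_mask = np.asarray(self.below_lod_mask, dtype=bool)
            if self.below_lod_mask.shape != self.values.shape:
                raise ValueError("below_lod_mask shape mismatch")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_chemicals(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, lod: dict[str, float] | None = None
                       ) -> "ExposureTable":
        ids = [str(c) for c in df.columns]
        lod_arr = None
        if lod is not None:
            lod_arr = np.array([lod[c] for c in ids], dtype=float)
        return cls(df.to_numpy(dtype=float), ids, lod=lod_arr)

    def impute(self, seed: int) -> "ExposureTable":
        """Impute all below-LOD entries column by column; returns a new table."""
        if self.lod is None:
            return self
        mask = self.below_lod_mask
        if mask is None:
            mask = self.values < self.lod[None, :]
        out = self.values.copy()
        ss = np.random.SeedSequence(seed)
        for j, child in enumerate(ss.spawn(self.n_chemicals)):
            if mask[:, j].any():
                out[:, j] = impute_below_lod(
                    self.values[:, j], self.lod[j],
                    rng=np.random.default_rng(child),
                    below_lod=mask[:, j],
                )
        return dataclasses.replace(self, values=out, below_lod_mask=None)


@dataclass
class QuantileMatrix:
    """Integer quantile scores, entries in {0, ..., Q-1}."""

    q: np.ndarray
    Q: int = 4
    chemical_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q)
        if self.Q < 2:
            raise ValueError("Q must be at least 2")
        if self.q.min() < 0 or self.q.max() > self.Q - 1:
            raise ValueError(f"quantile scores must lie in 0..{self.Q - 1}")

    @property
    def n_subjects(self) -> int:
        return self.q.shape[0]

    @property
    def n_chemicals(self) -> int:
        return self.q.shape[1]


@dataclass
class GroupStructure:
    """Ordered assignment of chemicals to exposure-group indices.

    ``assignment`` maps chemical name -> group position k (0-based);
    ``group_names`` fixes the group order; ``sizes[k]`` is the number of
    chemicals C_k in group k and ``thresholds[k] = 1/C_k`` is the equal-share
    importance threshold for that group.
    """

    assignment: dict[str, int]
    group_names: list[str]
    sizes: np.ndarray = field(init=False)
    thresholds: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        k = len(self.group_names)
        counts = np.zeros(k, dtype=int)
        for g in self.assignment.values():
            if not 0 <= g < k:
                raise ValueError(f"group index {g} out of range")
            counts[g] += 1
        if np.any(counts < 1):
            empty = [self.group_names[i] for i in np.flatnonzero(counts < 1)]
            raise ValueError(f"empty group(s): {empty}")
        self.sizes = counts
        self.thresholds = 1.0 / counts

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    @property
    def n_chemicals(self) -> int:
        return len(self.assignment)

    def member_indices(self, chemical_ids: list[str]) -> list[np.ndarray]:
        """Column indices into ``chemical_ids`` for each group, in order."""
        cols = []
        for k in range(self.n_groups):
            members = [i for i, c in enumerate(chemical_ids)
                       if self.assignment.get(c) == k]
            if len(members) != self.sizes[k]:
                missing = set(self.assignment) - set(chemical_ids)
                raise ValueError(
                    f"group {self.group_names[k]!r}: chemicals missing from the "
                    f"exposure table: {sorted(missing)}"
                )
            cols.append(np.array(members, dtype=int))
        return cols

    def chemicals_in(self, k: int) -> list[str]:
        return [c for c, g in self.assignment.items() if g == k]


@dataclass
class StudyData:
    """Binary outcome, optional covariates, quantile scores and grouping."""

    y: np.ndarray
    quantiles: QuantileMatrix
    groups: GroupStructure
    Z: np.ndarray | None = None
    covariate_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if not np.isin(self.y, [0, 1]).all():
            raise ValueError("outcome must be binary 0/1")
        self.y = self.y.astype(float)
        n = self.quantiles.n_subjects
        if self.y.shape != (n,):
            raise ValueError("outcome length does not match exposure rows")
        if self.Z is not None:
            self.Z = np.asarray(self.Z, dtype=float)
            if self.Z.size == 0:
                self.Z = None
            elif self.Z.shape[0] != n:
                raise ValueError("covariate rows do not match exposure rows")
        if self.groups.n_chemicals != self.quantiles.n_chemicals:
            raise ValueError("group assignment does not cover every chemical")

    @property
    def n_subjects(self) -> int:
        return self.y.shape[0]

    @property
    def n_covariates(self) -> int:
        return 0 if self.Z is None else self.Z.shape[1]

    def subset(self, idx: np.ndarray) -> "StudyData":
        return StudyData(
            y=self.y[idx],
            quantiles=QuantileMatrix(self.quantiles.q[idx], self.quantiles.Q,
                                     self.quantiles.chemical_ids),
            groups=self.groups,
            Z=None if self.Z is None else self.Z[idx],
            covariate_names=self.covariate_names,
        )


def quantize_exposures(table: ExposureTable, Q: int = 4) -> QuantileMatrix:
    """Bin each chemical's concentrations into Q quantile scores 0..Q-1.

    Subjects are ranked per chemical (ties get the average rank, so tied raw
    values always share a score) and cut at the empirical 1/Q, ..., (Q-1)/Q
    quantiles of the analysis sample: score = floor(Q * rank / (n + eps)).
    Scores are invariant under strictly monotone transforms of a column, and
    for n divisible by Q with no ties each level holds exactly n/Q subjects.
    """
    if Q < 2:
        raise ValueError("Q must be at least 2")
    n = table.n_subjects
    if Q > n:
        raise ValueError(f"cannot form {Q} quantiles from {n} subjects")
    x = table.values
    scores = np.empty(x.shape, dtype=np.int64)
    for j in range(table.n_chemicals):
        col = x[:, j]
        if np.ptp(col) == 0:
            raise ValueError(
                f"chemical {table.chemical_ids[j]!r} is constant; "
                "quantile scores are undefined"
            )
        ranks = stats.rankdata(col, method="average")
        scores[:, j] = np.minimum(
            Q - 1, np.floor(Q * ranks / (n + 1e-9)).astype(np.int64)
        )
    return QuantileMatrix(scores, Q, chemical_ids=list(table.chemical_ids))


def _censored_lognormal_mle(observed: np.ndarray, n_censored: int, lod: float
                            ) -> tuple[float, float]:
    """MLE of (mu, sigma) for lognormal data left-censored at ``lod``.

    Observed values contribute the lognormal density; each censored entry
    contributes log Phi((log lod - mu)/sigma).
    """
    logx = np.log(observed)
    loglod = np.log(lod)

    def nll(theta):
        mu, logsig = theta
        sig = np.exp(logsig)
        ll = np.sum(stats.norm.logpdf(logx, mu, sig)) - np.sum(logx)
        if n_censored:
            ll += n_censored * stats.norm.logcdf(loglod, mu, sig)
        return -ll

    x0 = np.array([logx.mean(), np.log(max(logx.std(), 1e-3))])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10})
    mu, sigma = res.x[0], float(np.exp(res.x[1]))
    return mu, sigma


def impute_below_lod(values: np.ndarray, lod: float,
                     seed: int | None = None,
                     rng: np.random.Generator | None = None,
                     below_lod: np.ndarray | None = None) -> np.ndarray:
    """Replace below-LOD entries with draws from a fitted truncated lognormal.

    A lognormal is fitted by maximum likelihood treating below-LOD entries as
    left-censored; censored entries are then replaced by draws from that
    lognormal truncated to (0, lod). Observed entries are returned unchanged
    and the result is deterministic given the seed.

    Raises ``ValueError`` when fewer than 20% of entries are detected, the
    usual inclusion rule — such a chemical should be excluded, not imputed.
    """
    values = np.asarray(values, dtype=float)
    if lod <= 0:
        raise ValueError("lod must be positive")
    if below_lod is None:
        below_lod = values < lod
    below_lod = np.asarray(below_lod, dtype=bool)
    n_cens = int(below_lod.sum())
    if n_cens == 0:
        return values.copy()
    detect_frac = 1.0 - n_cens / values.size
    if detect_frac < MIN_DETECT_FRACTION:
        raise ValueError(
            f"only {detect_frac:.0%} of measurements are above the LOD; "
            "chemicals detected in fewer than 20% of samples should be "
            "excluded rather than imputed"
        )
    observed = values[~below_lod]
    if np.any(observed <= 0):
        raise ValueError("observed concentrations must be positive")
    mu, sigma = _censored_lognormal_mle(observed, n_cens, lod)
    if rng is None:
        rng = np.random.default_rng(seed)
    # inverse-CDF draw from the lognormal restricted to (0, lod)
    p_lod = stats.norm.cdf((np.log(lod) - mu) / sigma)
    u = rng.uniform(0.0, p_lod, size=n_cens)
    draws = np.exp(mu + sigma * stats.norm.ppf(u))
    out = values.copy()
    out[below_lod] = np.clip(draws, np.nextafter(0, 1), np.nextafter(lod, 0))
    return out


def build_group_structure(assignment: dict[str, str],
                          group_order: list[str] | None = None
                          ) -> GroupStructure:
    """Build a :class:`GroupStructure` from a chemical -> group-name map."""
    if group_order is None:
        seen: dict[str, None] = {}
        for g in assignment.values():
            seen.setdefault(g, None)
        group_order = list(seen)
    if len(set(group_order)) != len(group_order):
        raise ValueError("group names must be unique")
    index = {g: k for k, g in enumerate(group_order)}
    unknown = {g for g in assignment.values() if g not in index}
    if unknown:
        raise ValueError(f"groups not in group_order: {sorted(unknown)}")
    return GroupStructure(
        assignment={c: index[g] for c, g in assignment.items()},
        group_names=list(group_order),
    )


def read_exposures(path) -> ExposureTable:
    """Read an exposure CSV whose header row holds the chemical ids."""
    df = pd.read_csv(path, comment="#")
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax())
        raise ValueError(f"missing exposure value at data row {bad}")
    return ExposureTable.from_dataframe(df)


def read_group_map(path) -> dict[str, str]:
    """Read a two-column (chemical, group) CSV into a dict."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] != 2:
        raise ValueError("group map must have exactly two columns")
    chems = df.iloc[:, 0].astype(str)
    if chems.duplicated().any():
        dup = chems[chems.duplicated()].iloc[0]
        raise ValueError(f"chemical {dup!r} assigned to more than one group")
    return dict(zip(chems, df.iloc[:, 1].astype(str)))


def read_lod(path) -> dict[str, float]:
    """Read a two-column (chemical, lod) CSV into a dict."""
    df = pd.read_csv(path, comment="#")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))
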