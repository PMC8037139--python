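"""MCMC convergence diagnostics: Gelman-Rubin PSRF and Geweke z-scores.

The Gelman-Rubin potential scale reduction factor (PSRF) compares the
between- and within-chain variance of a scalar parameter; values near 1
indicate the chains have mixed. Convergence is declared when the 97.5% upper
bound of the PSRF is below 1.10 for every parameter. By default each chain is
additionally split in half, so within-chain nonstationarity also inflates the
statistic. Weight simplices are diagnosed on within-group log ratios
log(w_j / w_C), the unconstrained scale the sampler moves on.

The Geweke diagnostic compares the mean of an early window of a single chain
with the mean of a late window via a two-sample z-score whose standard errors
come from spectral density estimates at frequency zero (Bartlett-windowed
autocovariances), which accounts for autocorrelation within each window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .sampler import PosteriorDraws

__all__ = ["gelman_rubin", "gelman_rubin_scalar", "geweke", "geweke_table",
           "PSRF_THRESHOLD"]

#: conventional convergence criterion: PSRF upper bound below this
PSRF_THRESHOLD = 1.10


def gelman_rubin_scalar(chains: np.ndarray, split: bool = True
                        ) -> tuple[float, float]:
    """PSRF point estimate and 97.5% upper bound for one scalar parameter.

    Parameters
    ----------
    chains : ndarray, shape (m, n)
        m >= 2 chains of n retained draws each.
    split : bool
        Split each chain in half first (default), so the diagnostic is also
        sensitive to trends within a chain.

    Returns
    -------
    (psrf, upper) following the Gelman-Rubin formulation with the
    degrees-of-freedom correction; the upper bound uses the F-distribution
    quantile for the between/within variance ratio.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2:
        raise ValueError("chains must be a 2-D (m, n) array")
    if x.shape[0] < 2:
        raise ValueError("Gelman-Rubin requires at least two chains")
    if x.shape[1] < 10:
        raise ValueError("need at least 10 retained draws per chain")
    if split:
        half = x.shape[1] // 2
        x = np.vstack([x[:, :half], x[:, half:2 * half]])
    m, n = x.shape

    xbar = x.mean(axis=1)
    s2 = x.var(axis=1, ddof=1)
    W = s2.mean()
    B = n * xbar.var(ddof=1)
    if W <= 0.0 or B <= 0.0:
        # degenerate: constant chains or exactly identical chains
        return 1.0, 1.0

    muhat = xbar.mean()
    var_w = s2.var(ddof=1) / m
    var_b = 2.0 * B ** 2 / (m - 1)
    cov_wb = (n / m) * (np.cov(s2, xbar ** 2, ddof=1)[0, 1]
                        - 2.0 * muhat * np.cov(s2, xbar, ddof=1)[0, 1])

    sig2hat = (n - 1) / n * W + B / n
    Vhat = sig2hat + B / (m * n)
    var_V = ((n - 1) ** 2 * var_w + (1 + 1 / m) ** 2 * var_b
             + 2 * (n - 1) * (1 + 1 / m) * cov_wb) / n ** 2
    df_V = 2.0 * Vhat ** 2 / var_V if var_V > 0 else np.inf
    df_adj = (df_V + 3.0) / (df_V + 1.0)

    r2_fixed = (n - 1) / n
    r2_random = (1.0 + 1.0 / m) * B / (n * W)
    psrf = float(np.sqrt(df_adj * (r2_fixed + r2_random)))
    if var_w > 0:
        df_w = 2.0 * W ** 2 / var_w
        fq = stats.f.ppf(0.975, m - 1, df_w)
        upper = float(np.sqrt(df_adj * (r2_fixed + fq * r2_random)))
    else:
        upper = psrf
    return psrf, upper


def gelman_rubin(draws: PosteriorDraws, split: bool = True) -> pd.DataFrame:
    """PSRF table for every scalar parameter of a posterior sample.

    Returns a frame with columns (parameter, psrf, upper, converged); weight
    simplices appear as within-group log-ratio parameters. Raises on a
    single-chain sample.
    """
    if draws.n_chains < 2:
        raise ValueError("Gelman-Rubin requires at least two chains")
    rows = []
    items = [(nm, arr) for nm, arr in draws.scalar_params()
             if not nm.startswith("w[")]
    items += list(draws.weight_logratios())
    for name, arr in items:
        psrf, upper = gelman_rubin_scalar(arr, split=split)
        rows.append({"parameter": name, "psrf": psrf, "upper": upper,
                     "converged": upper < PSRF_THRESHOLD})
    return pd.DataFrame(rows)


def _spectral_var(x: np.ndarray, max_lag: int | None = None) -> float:
    """Spectral density at frequency zero via Bartlett-windowed autocovariance
    (an estimate of the long-run variance of the mean, times n)."""
    n = len(x)
    if max_lag is None:
        max_lag = int(np.sqrt(n))
    max_lag = min(max_lag, n - 1)
    xc = x - x.mean()
    s = xc @ xc / n
    for lag in range(1, max_lag + 1):
        gamma = xc[:-lag] @ xc[lag:] / n
        s += 2.0 * (1.0 - lag / (max_lag + 1.0)) * gamma
    return max(s, 0.0)


def geweke(chain: np.ndarray, frac_a: float = 0.1, frac_b: float = 0.5,
           max_lag: int | None = None) -> float:
    """Geweke convergence z-score for a single chain.

    Compares the mean of the first ``frac_a`` of the chain with the mean of
    the last ``frac_b``: z = (mean_a - mean_b) / sqrt(se_a^2 + se_b^2), with
    spectral-density standard errors (``max_lag=0`` reduces them to the naive
    iid standard errors). |z| > 2-3 suggests the start of the chain has not
    converged to the same distribution as the end.
    """
    x = np.asarray(chain, dtype=float).ravel()
    n = len(x)
    if frac_a <= 0 or frac_b <= 0 or frac_a + frac_b > 1.0:
        raise ValueError("window fractions must be positive and the windows "
                         "must not overlap (frac_a + frac_b <= 1)")
    na = int(np.floor(frac_a * n))
    nb = int(np.floor(frac_b * n))
    if na < 2 or nb < 2:
        raise ValueError("chain too short for the requested windows")
    a = x[:na]
    b = x[n - nb:]
    var_a = _spectral_var(a, max_lag) / na
    var_b = _spectral_var(b, max_lag) / nb
    return float((a.mean() - b.mean()) / np.sqrt(var_a + var_b))


def geweke_table(draws: PosteriorDraws, frac_a: float = 0.1,
                 frac_b: float = 0.5) -> pd.DataFrame:
    """Geweke z-scores for every scalar parameter, one row per chain."""
    rows = []
    items = [(nm, arr) for nm, arr in draws.scalar_params()
             if not nm.startswith("w[")]
    items += list(draws.weight_logratios())
    for name, arr in items:
        for chain in range(arr.shape[0]):
            rows.append({"parameter": name, "chain": chain,
                         "z": geweke(arr[chain], frac_a, frac_b)})
    return pd.DataFrame(rows)
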