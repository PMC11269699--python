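"""Shared statistical kernel.

All hypothesis tests in the pipeline are two-sided at alpha = 0.05:
least-squares slopes with a Wald t test, Spearman rank correlation,
the non-parametric Mann-Kendall trend test (tie-corrected variance,
continuity correction), and the two-sample Kolmogorov-Smirnov test.
Decile summaries report per-bin medians with bootstrap-percentile 95%
confidence intervals while correlation/significance are always computed
on the unbinned data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass(frozen=True)
class SlopeFit:
    slope: float
    se: float
    p: float
    intercept: float
    n: int

    @property
    def significant(self) -> bool:
        return bool(self.p < ALPHA)


@dataclass(frozen=True)
class TrendResult:
    s: int
    p: float
    direction: str  # "increasing" | "decreasing" | "no trend"
    relative_change_pct: float

    @property
    def significant(self) -> bool:
        return bool(self.p < ALPHA)


def spearman(x, y):
    """Spearman rank correlation (average ranks for ties) and two-sided
    t-approximation p-value.  Returns (nan, nan) with a warning when either
    vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("spearman undefined for a constant vector", stacklevel=2)
        return np.nan, np.nan
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def ols_slope_wald(x, y) -> SlopeFit:
    """Simple least-squares slope with Wald t test (n-2 df, two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: slope undefined")
    res = sps.linregress(x, y)
    return SlopeFit(
        slope=float(res.slope),
        se=float(res.stderr),
        p=float(res.pvalue),
        intercept=float(res.intercept),
        n=int(x.size),
    )


def mann_kendall(series) -> TrendResult:
    """Mann-Kendall trend test.

    S is the sum of sign(x_j - x_i) over all i < j pairs; its variance
    uses the standard tie correction and the p-value comes from the
    normal approximation with continuity correction.  The relative
    change over the period is 100*(last - first)/first.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("Mann-Kendall needs n >= 4")
    diffs = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diffs, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var <= 0 or s == 0:
        p = 1.0
        direction = "no trend"
    else:
        z = (s - np.sign(s)) / np.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
        direction = "increasing" if s > 0 else "decreasing"
    if p >= ALPHA and direction != "no trend":
        pass  # direction reported regardless; significance is a separate flag
    rel = 100.0 * (x[-1] - x[0]) / x[0] if x[0] != 0 else np.nan
    return TrendResult(s=s, p=p, direction=direction, relative_change_pct=float(rel))


def ks_two_sample(a, b, exact_max_nm: int = 10_000):
    """Two-sample Kolmogorov-Smirnov statistic and p.

    Uses the exact small-sample distribution when n*m <= ``exact_max_nm``
    and the asymptotic one otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    method = "exact" if a.size * b.size <= exact_max_nm else "asymp"
    res = sps.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def assign_deciles(by) -> np.ndarray:
    """Decile bin (0..9) of each observation by its rank in ``by``.

    Tied values all receive the bin of the lowest-ranked occurrence, so
    equal inputs never straddle a bin boundary; with distinct values the
    bin sizes differ by at most one.
    """
    by = np.asarray(by, dtype=float)
    n = by.size
    order = np.argsort(by, kind="mergesort")
    bins_sorted = (np.arange(n) * 10) // n
    bins = np.empty(n, dtype=int)
    bins[order] = bins_sorted
    # ties -> lower bin
    uniq, inv = np.unique(by, return_inverse=True)
    min_bin = np.full(uniq.size, 9)
    np.minimum.at(min_bin, inv, bins)
    return min_bin[inv]


def decile_summaries(values, by, n_boot: int = 1000, seed=None) -> pd.DataFrame:
    """Per-decile medians of ``values`` grouped by deciles of ``by``.

    Returns one row per decile with the count, the median and a 95%
    bootstrap percentile confidence interval (``n_boot`` resamples,
    seeded).  The full-sample Spearman r and p of values vs by are
    attached as ``DataFrame.attrs['spearman_r'] / ['spearman_p']``
    because binning is for display only.
    """
    values = np.asarray(values, dtype=float)
    by = np.asarray(by, dtype=float)
    if values.size != by.size or values.size < 10:
        raise ValueError("need matched vectors with n >= 10")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable confidence intervals", stacklevel=2)
    rng = np.random.default_rng(seed)
    bins = assign_deciles(by)
    rows = []
    for d in range(10):
        v = values[bins == d]
        if v.size == 0:
            rows.append({"decile": d + 1, "n": 0, "median": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan})
            continue
        med = float(np.median(v))
        boots = np.median(
            rng.choice(v, size=(n_boot, v.size), replace=True), axis=1
        )
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append({"decile": d + 1, "n": int(v.size), "median": med,
                     "ci_low": float(min(lo, med)), "ci_high": float(max(hi, med))})
    out = pd.DataFrame(rows)
    r, p = spearman(by, values)
    out.attrs["spearman_r"] = r
    out.attrs["spearman_p"] = p
    return out


def missingness_correlation(flags: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Spearman r between binary missingness indicators and covariates.

    ``flags`` holds one boolean column per characteristic (True =
    missing); ``covariates`` numeric columns aligned on the same index.
    Pairs where the flag is constant are returned with NaN and flagged.
    """
    rows = []
    for fcol in flags.columns:
        f = flags[fcol].astype(float)
        for ccol in covariates.columns:
            c = pd.to_numeric(covariates[ccol], errors="coerce")
            ok = c.notna()
            if f[ok].nunique() < 2 or ok.sum() < 3:
                rows.append({"missing_flag": fcol, "covariate": ccol,
                             "spearman_r": np.nan, "p": np.nan, "defined": False})
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r, p = spearman(f[ok].to_numpy(), c[ok].to_numpy())
            rows.append({"missing_flag": fcol, "covariate": ccol,
                         "spearman_r": r, "p": p, "defined": bool(np.isfinite(r))})
    return pd.DataFrame(rows)
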