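"""Group summaries (mean +/- SD) and nonparametric CONT-vs-MCT comparisons.

The two tests used throughout are the two-sided Mann-Whitney U test and
Kruskal-Wallis ANOVA, with significance declared at alpha = 0.05 and no
multiple-testing correction by default (an optional Holm adjustment is
available).  The test engines are the SciPy implementations; an exact null
distribution is used for small tie-free samples and the tie- and
continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, ParameterError

__all__ = ["GroupSummary", "ComparisonResult", "mann_whitney",
           "kruskal_wallis", "summarize"]

ALPHA = 0.05
#: largest per-sample size for which the exact MWU null is used by default
EXACT_N = 8


@dataclass(frozen=True)
class GroupSummary:
    characteristic: str
    group: str
    n: int
    mean: float
    sd: float
    units: str = ""

    def __post_init__(self):
        if self.n < 1:
            raise DataError("group summary needs n >= 1")
        if self.sd < 0:
            raise DataError("sd must be >= 0")


@dataclass(frozen=True)
class ComparisonResult:
    test: str                       # "MWU" or "KW"
    statistic: float
    p_value: float
    significant: bool
    alpha: float = ALPHA

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise DataError(f"p-value out of range: {self.p_value}")


def _clean(sample, name):
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise DataError(f"sample {name!r} is empty")
    if np.any(~np.isfinite(x)):
        x = x[np.isfinite(x)]
        if x.size == 0:
            raise DataError(f"sample {name!r} has no finite values")
    return x


def mann_whitney(x, y, alpha: float = ALPHA,
                 method: str = "auto") -> ComparisonResult:
    """Two-sided Mann-Whitney U comparison of two independent samples.

    ``method='auto'`` uses the exact null distribution when both samples
    have <= 8 observations and the pooled data are tie-free, and the normal
    approximation with tie and continuity corrections otherwise.
    """
    x, y = _clean(x, "x"), _clean(y, "y")
    if min(x.size, y.size) < 3:
        raise ParameterError("each sample must have n >= 3")
    if method == "auto":
        ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
        method = ("exact" if x.size <= EXACT_N and y.size <= EXACT_N
                  and not ties else "asymptotic")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    p = float(min(res.pvalue, 1.0))
    return ComparisonResult("MWU", float(res.statistic), p, p < alpha, alpha)


def kruskal_wallis(groups, alpha: float = ALPHA) -> ComparisonResult:
    """Kruskal-Wallis H test (tie-corrected, chi-square reference)."""
    cleaned = [_clean(g, f"group {i}") for i, g in enumerate(groups)]
    cleaned = [g for g in cleaned if g.size > 0]
    if len(cleaned) < 2:
        raise ParameterError("need >= 2 non-empty groups")
    if any(g.size < 3 for g in cleaned):
        raise ParameterError("each group must have n >= 3")
    if all(np.array_equal(g, cleaned[0]) for g in cleaned[1:]) and \
            np.unique(cleaned[0]).size == 1:
        # all observations identical: H = 0 by definition, SciPy refuses
        return ComparisonResult("KW", 0.0, 1.0, False, alpha)
    res = sps.kruskal(*cleaned)
    p = float(res.pvalue)
    return ComparisonResult("KW", float(res.statistic), p, p < alpha, alpha)


def _holm(pvals):
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj


def summarize(feature_table: pd.DataFrame,
              value_col: str = "value",
              characteristic_col: str = "characteristic",
              group_col: str = "group",
              preload_col: str | None = "preload_pct",
              units_col: str | None = "units",
              test: str = "MWU",
              alpha: float = ALPHA,
              holm: bool = False) -> pd.DataFrame:
    """Mean +/- SD per group per characteristic (per preload), with a
    CONT-vs-MCT comparison attached to every cell.

    Expects a tidy table with one row per muscle per characteristic.
    Groups with n < 3 are summarized but their comparison is skipped.
    Returns a DataFrame with columns {characteristic, preload_pct, group, n,
    mean, sd, units, test, statistic, p, significant}.
    """
    if value_col not in feature_table.columns:
        raise DataError(f"feature table lacks a {value_col!r} column")
    keys = [characteristic_col]
    if preload_col is not None and preload_col in feature_table.columns:
        keys.append(preload_col)
    rows = []
    pvals, prow_idx = [], []
    for key, cell in feature_table.groupby(keys, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        samples = {g: sub[value_col].to_numpy(dtype=float)
                   for g, sub in cell.groupby(group_col)}
        comparable = {g: s[np.isfinite(s)] for g, s in samples.items()}
        run_test = (len(comparable) == 2
                    and all(len(s) >= 3 for s in comparable.values()))
        cmp_res = None
        if run_test:
            a, b = (comparable[g] for g in sorted(comparable))
            try:
                cmp_res = (mann_whitney(a, b, alpha=alpha) if test == "MWU"
                           else kruskal_wallis([a, b], alpha=alpha))
            except (DataError, ParameterError):
                cmp_res = None
        for g, s in samples.items():
            s = s[np.isfinite(s)]
            if len(s) == 1:
                warnings.warn(f"single-muscle group {g!r}; reporting sd = 0",
                              stacklevel=2)
            units = ""
            if units_col and units_col in cell.columns:
                units = str(cell[units_col].iloc[0])
            row = {
                characteristic_col: key[0],
                "preload_pct": key[1] if len(keys) > 1 else np.nan,
                "group": g, "n": len(s),
                "mean": float(np.mean(s)) if len(s) else np.nan,
                "sd": float(np.std(s, ddof=1)) if len(s) > 1 else 0.0,
                "units": units,
                "test": cmp_res.test if cmp_res else "",
                "statistic": cmp_res.statistic if cmp_res else np.nan,
                "p": cmp_res.p_value if cmp_res else np.nan,
                "significant": cmp_res.significant if cmp_res else False,
            }
            rows.append(row)
            if cmp_res is not None:
                pvals.append(cmp_res.p_value)
                prow_idx.append(len(rows) - 1)
    out = pd.DataFrame(rows)
    if holm and pvals:
        # one p per cell; adjust the distinct cell p-values, then re-flag
        cell_p = {}
        for i in prow_idx:
            cell_key = (out.loc[i, characteristic_col], out.loc[i, "preload_pct"])
            cell_p[cell_key] = out.loc[i, "p"]
        keys_, ps = zip(*cell_p.items())
        adj = dict(zip(keys_, _holm(np.array(ps))))
        for i in prow_idx:
            cell_key = (out.loc[i, characteristic_col], out.loc[i, "preload_pct"])
            out.loc[i, "p"] = adj[cell_key]
            out.loc[i, "significant"] = adj[cell_key] < alpha
    return out
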