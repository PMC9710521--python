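"""Item-level descriptives, the informativeness screen, reliability and
between-group comparisons.

These are the checks run before any network is estimated: moments of every
item, exclusion of items whose spread is an outlier on the low side
(standard deviation more than 2.5 SDs below the mean item SD), Cronbach's
alpha per scale, and per-item Welch t-tests between the two school groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "item_moments",
    "informativeness_screen",
    "cronbach_alpha",
    "group_t_tests",
]


def item_moments(data: pd.DataFrame, items: list[str] | None = None) -> pd.DataFrame:
    """Mean, SD (n-1), moment skewness g1 and excess kurtosis g2 per item.

    For a constant item the SD is 0 and skewness/kurtosis are undefined,
    reported as NaN; the informativeness screen only consumes SDs, so the
    NaNs never propagate into exclusion decisions.
    """
    if items is None:
        items = [c for c in data.columns if c not in ("group", "sex")]
    rows = []
    for it in items:
        x = np.asarray(data[it], dtype=float)
        if x.size < 2:
            raise ValueError(f"item {it!r} needs at least 2 observations")
        m = x.mean()
        d = x - m
        m2 = np.mean(d**2)
        if m2 == 0.0:
            g1 = g2 = np.nan
        else:
            g1 = np.mean(d**3) / m2**1.5
            g2 = np.mean(d**4) / m2**2 - 3.0
        rows.append(
            {
                "item": it,
                "mean": m,
                "sd": x.std(ddof=1),
                "skewness": g1,
                "kurtosis": g2,
            }
        )
    return pd.DataFrame(rows).set_index("item")


def informativeness_screen(summaries: pd.DataFrame) -> set[str]:
    """Items whose SD falls more than 2.5 SDs below the mean item SD.

    The rule is scale-equivariant: rescaling all items by a common positive
    factor leaves the exclusion set unchanged.
    """
    sds = summaries["sd"].to_numpy(dtype=float)
    if sds.size < 2:
        raise ValueError("need at least 2 items to screen")
    cutoff = sds.mean() - 2.5 * sds.std(ddof=1)
    return {it for it, sd in zip(summaries.index, sds) if sd < cutoff}


def cronbach_alpha(data: pd.DataFrame, items: list[str]) -> float:
    """Cronbach's alpha of a scale: k/(k-1) * (1 - sum(var_i)/var(total))."""
    if len(items) < 2:
        raise ValueError("alpha needs at least 2 items")
    X = data[items].to_numpy(dtype=float)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance")
    k = len(items)
    return float(k / (k - 1) * (1.0 - X.var(axis=0, ddof=1).sum() / total_var))


def group_t_tests(
    data: pd.DataFrame,
    items: list[str] | None = None,
    group_col: str = "group",
) -> pd.DataFrame:
    """Welch two-sample t-test per item between the two groups.

    Returns one row per item with the two group means, Welch t, its
    degrees of freedom, and the two-sided p-value.  Welch (unequal
    variances) is used because the group sizes and spreads differ.
    """
    groups = sorted(pd.unique(data[group_col]).tolist())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {len(groups)}")
    if items is None:
        items = [c for c in data.columns if c not in (group_col, "sex")]
    a = data[data[group_col] == groups[0]]
    b = data[data[group_col] == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 rows")
    rows = []
    for it in items:
        xa = np.asarray(a[it], dtype=float)
        xb = np.asarray(b[it], dtype=float)
        res = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append(
            {
                "item": it,
                f"mean_{groups[0]}": xa.mean(),
                f"mean_{groups[1]}": xb.mean(),
                "t": float(res.statistic),
                "df": float(res.df),
                "p": float(res.pvalue),
            }
        )
    return pd.DataFrame(rows).set_index("item")
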