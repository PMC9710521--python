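"""Permutation network comparison and sensitivity analyses.

The network comparison test (NCT) contrasts two groups' networks on two
omnibus statistics: M, the maximum absolute difference in any edge weight
(structure invariance), and S, the absolute difference in global strength.
Group labels are permuted over the pooled rows, both networks re-estimated
from scratch (including EBIC re-selection) for every permutation, and
p-values use the add-one rule (1 + exceedances) / (1 + n_perm), with ties
counted as exceedances.

Also here: covariate adjustment by residualizing items on a covariate
before estimation, Spearman correlation between two networks' edge
vectors, and the random-subsample sensitivity analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .network import RESERVED_COLS, NetworkResults, estimate_network
from .stability import _fast_weights, _resample_ok

__all__ = [
    "NCTResult",
    "nct",
    "nct_from_groups",
    "covariate_adjust",
    "network_correlation",
    "subsample_sensitivity",
]


@dataclass
class NCTResult:
    """Observed NCT statistics, permutation distributions and p-values."""

    m_obs: float
    s_obs: float
    p_m: float
    p_s: float
    m_perm: np.ndarray = field(repr=False)
    s_perm: np.ndarray = field(repr=False)
    group_global_strengths: tuple[float, float]
    n_perm: int
    seed: int | None

    def to_json(self, path: str | Path) -> None:
        qs = [0.5, 0.9, 0.95, 0.99]
        payload = {
            "m_obs": self.m_obs,
            "s_obs": self.s_obs,
            "p_m": self.p_m,
            "p_s": self.p_s,
            "group_global_strengths": list(self.group_global_strengths),
            "n_perm": self.n_perm,
            "seed": self.seed,
            "m_perm_quantiles": {str(q): float(np.quantile(self.m_perm, q)) for q in qs},
            "s_perm_quantiles": {str(q): float(np.quantile(self.s_perm, q)) for q in qs},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    def summary(self) -> str:
        gs_a, gs_b = self.group_global_strengths
        return (
            "Network comparison test "
            f"({self.n_perm} permutations)\n"
            f"  max edge difference   M = {self.m_obs:.3f}   p = {self.p_m:.3f}\n"
            f"  global strength diff  S = {self.s_obs:.3f}   p = {self.p_s:.3f}\n"
            f"  global strengths: {gs_a:.3f} vs {gs_b:.3f}"
        )


def _items_of(data: pd.DataFrame, items: list[str] | None) -> list[str]:
    if items is None:
        items = [c for c in data.columns if c not in RESERVED_COLS]
    return list(items)


def nct(
    data_a: pd.DataFrame,
    data_b: pd.DataFrame,
    items: list[str] | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
) -> NCTResult:
    """Two-group network comparison test.

    The pooled rows are put in a canonical (lexicographic) order before
    permuting, so the test is symmetric in group order: same seed, same
    p-values either way.  Each permutation splits the pool into groups of
    the original sizes and re-runs the full estimator on both halves.
    """
    items = _items_of(data_a, items)
    if set(items) - set(data_b.columns):
        raise ValueError("groups have mismatched item sets")
    Xa = data_a[items].to_numpy(dtype=float)
    Xb = data_b[items].to_numpy(dtype=float)
    na, nb = len(Xa), len(Xb)
    if min(na, nb) <= len(items):
        raise ValueError("each group needs more rows than items")
    iu = np.triu_indices(len(items), k=1)

    def stats_of(X1, X2):
        W1 = _fast_weights(X1, gamma, n_lambda, lambda_min_ratio)
        W2 = _fast_weights(X2, gamma, n_lambda, lambda_min_ratio)
        gs1 = float(np.abs(W1[iu]).sum())
        gs2 = float(np.abs(W2[iu]).sum())
        m = float(np.abs(W1 - W2).max())
        return m, abs(gs1 - gs2), gs1, gs2

    m_obs, s_obs, gs_a, gs_b = stats_of(Xa, Xb)

    pool = np.vstack([Xa, Xb])
    pool = pool[np.lexsort(pool.T[::-1])]  # canonical row order
    n_small = min(na, nb)
    rng = np.random.default_rng(seed)
    m_perm = np.empty(n_perm)
    s_perm = np.empty(n_perm)
    for b in range(n_perm):
        for _ in range(11):
            perm = rng.permutation(pool.shape[0])
            X1, X2 = pool[perm[:n_small]], pool[perm[n_small:]]
            if _resample_ok(X1) and _resample_ok(X2):
                break
        m_perm[b], s_perm[b], _, _ = stats_of(X1, X2)
    p_m = float((1 + np.sum(m_perm >= m_obs)) / (1 + n_perm))
    p_s = float((1 + np.sum(s_perm >= s_obs)) / (1 + n_perm))
    return NCTResult(
        m_obs=m_obs,
        s_obs=s_obs,
        p_m=p_m,
        p_s=p_s,
        m_perm=m_perm,
        s_perm=s_perm,
        group_global_strengths=(gs_a, gs_b),
        n_perm=n_perm,
        seed=seed,
    )


def nct_from_groups(
    data: pd.DataFrame, group_col: str = "group", **kwargs
) -> NCTResult:
    """Run the NCT on the two groups of a stacked table."""
    groups = sorted(pd.unique(data[group_col]).tolist())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {len(groups)}")
    a = data[data[group_col] == groups[0]]
    b = data[data[group_col] == groups[1]]
    return nct(a, b, **kwargs)


def covariate_adjust(
    data: pd.DataFrame,
    covariate: str = "sex",
    items: list[str] | None = None,
) -> pd.DataFrame:
    """Residualize every item on a covariate by least squares.

    Returns a copy of the table with item columns replaced by residuals
    (continuous); estimating a network on the result is equivalent to
    partialling the covariate out of the correlations.
    """
    if covariate not in data.columns:
        raise ValueError(f"covariate column {covariate!r} not found")
    c = data[covariate].to_numpy(dtype=float)
    if c.std() == 0:
        raise ValueError("covariate is constant")
    items = _items_of(data.drop(columns=[covariate]), items)
    Z = np.column_stack([np.ones(len(c)), c])
    out = data.copy()
    for it in items:
        y = data[it].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        if resid.std() <= 1e-10 * (1.0 + y.std()):
            raise ValueError(
                f"item {it!r} has constant residual after adjusting for {covariate!r}"
            )
        out[it] = resid
    return out


def network_correlation(
    net_a: NetworkResults, net_b: NetworkResults
) -> tuple[float, float]:
    """Spearman correlation between two networks' edge-weight vectors.

    Compares upper-triangle weights of networks on the same node set;
    returns (rho, two-sided p) with the large-sample t approximation.
    """
    if net_a.items != net_b.items:
        raise ValueError("networks are on different node sets")
    ea, eb = net_a.edge_vector(), net_b.edge_vector()
    if ea.size < 3:
        raise ValueError("need at least 3 edge slots")
    res = stats.spearmanr(ea, eb)
    return float(res.statistic), float(res.pvalue)


def subsample_sensitivity(
    data: pd.DataFrame,
    fraction: float = 0.3,
    n_perm: int = 1000,
    seed: int | None = None,
    items: list[str] | None = None,
    **est_kwargs,
) -> dict:
    """Random-subsample sensitivity check of a network.

    Draws round(fraction * n) rows without replacement, estimates the
    subsample network, and reports its Spearman correlation with the
    full-sample network plus the NCT between subsample and full sample.
    (The subsample overlaps the full sample; the comparison mirrors the
    published procedure rather than an independent-samples test.)
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    items = _items_of(data, items)
    rng = np.random.default_rng(seed)
    n = len(data)
    m = round(fraction * n)
    if m <= len(items):
        raise ValueError("subsample smaller than the number of items")
    idx = rng.choice(n, m, replace=False)
    sub = data.iloc[np.sort(idx)]
    net_full = estimate_network(data, items=items, **est_kwargs)
    net_sub = estimate_network(sub, items=items, **est_kwargs)
    rho, p = network_correlation(net_full, net_sub)
    seed_nct = int(rng.integers(2**31))
    result = nct(sub, data, items=items, n_perm=n_perm, seed=seed_nct, **est_kwargs)
    return {
        "fraction": fraction,
        "spearman_rho": rho,
        "spearman_p": p,
        "nct": result,
        "network_full": net_full,
        "network_subsample": net_sub,
    }
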