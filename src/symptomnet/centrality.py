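"""Node-importance measures for symptom networks.

Strength is the sum of a node's absolute edge weights; bridge strength the
part of that sum crossing community (scale) boundaries; predictability the
in-sample R-squared of regressing each item on all others.  Standardized
(z) scores use the n-1 denominator across nodes, and a node qualifies as a
bridge symptom when its z bridge strength is at least 1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["strength", "bridge_strength", "predictability", "BRIDGE_Z_CUTOFF"]

#: screening rule: bridge symptoms have standardized bridge strength >= 1
BRIDGE_Z_CUTOFF = 1.0


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        warnings.warn("all values equal; z-scores reported as zeros", stacklevel=3)
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def strength(weights: np.ndarray, items: list[str]) -> pd.DataFrame:
    """Per-node strength and its z-score across nodes."""
    W = np.asarray(weights, dtype=float)
    if W.shape[0] < 2:
        raise ValueError("strength needs at least 2 nodes")
    s = np.abs(W).sum(axis=0)
    return pd.DataFrame(
        {"strength": s, "z_strength": _zscore(s)}, index=pd.Index(items, name="item")
    )


def bridge_strength(
    weights: np.ndarray, items: list[str], communities: dict[str, str]
) -> pd.DataFrame:
    """Per-node cross-community strength, z-score, and the screened flag.

    z-scores are pooled across all nodes (not within community); the
    screened set is ``z >= 1``.
    """
    W = np.abs(np.asarray(weights, dtype=float))
    comm = [communities[it] for it in items]
    if len(set(comm)) < 2:
        raise ValueError("bridge strength needs at least 2 communities")
    cross = np.array([[ci != cj for cj in comm] for ci in comm])
    b = (W * cross).sum(axis=1)
    z = _zscore(b)
    return pd.DataFrame(
        {"bridge_strength": b, "z_bridge": z, "is_bridge": z >= BRIDGE_Z_CUTOFF},
        index=pd.Index(items, name="item"),
    )


def predictability(data: pd.DataFrame, items: list[str]) -> pd.Series:
    """In-sample R-squared of each item's OLS regression on the others.

    Raw scores are used (items treated as continuous, matching the network
    estimator); R-squared is floored at 0.  Collinear predictors are
    tolerated via the minimum-norm solution — R-squared stays well defined
    even when individual coefficients are not (e.g. a duplicated item).
    """
    X = data[list(items)].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more rows than items")
    out = {}
    for i, it in enumerate(items):
        y = X[:, i]
        Z = np.column_stack([np.ones(n), np.delete(X, i, axis=1)])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        tss = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / tss if tss > 0 else 0.0
        out[it] = max(0.0, float(r2))
    return pd.Series(out, name="predictability").rename_axis("item")
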