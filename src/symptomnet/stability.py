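"""Bootstrap accuracy and stability of estimated networks.

Three procedures, all re-running the full estimator (correlation ->
penalty path -> EBIC selection) on every resample:

* nonparametric bootstrap of edge weights -> per-edge quantile CIs;
* bootstrap difference tests between pairs of edges and pairs of node
  strengths (significant when the 95% CI of the difference excludes 0);
* case-dropping bootstrap -> correlation-stability (CS) coefficient: the
  largest fraction of cases droppable such that, with 95% probability, the
  subsampled strength vector still correlates >= 0.7 with the original.

Degenerate resamples (a constant item column) are re-drawn up to 10 times
and then dropped with a warning, so reports always state how many
replicates they aggregate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .glasso import glasso_path, partial_correlations
from .network import RESERVED_COLS

__all__ = [
    "StabilityReport",
    "edge_accuracy",
    "difference_tests",
    "case_dropping",
    "cs_coefficient",
    "stability_report",
    "DEFAULT_DROP_GRID",
]

#: case-dropping proportions 0.05 .. 0.75 in steps of 0.05 (the grid cap is
#: why reported CS values max out at 0.75)
DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.76, 0.05), 2))

_MAX_REDRAWS = 10


def _fast_weights(X: np.ndarray, gamma: float, n_lambda: int, ratio: float) -> np.ndarray:
    S = np.corrcoef(X, rowvar=False)
    res = glasso_path(S, X.shape[0], gamma=gamma, n_lambda=n_lambda, lambda_min_ratio=ratio)
    return partial_correlations(res["theta"])


def _resample_ok(X: np.ndarray) -> bool:
    return bool(np.all(X.std(axis=0) > 0))


def _get_X(data: pd.DataFrame, items: list[str] | None) -> tuple[np.ndarray, list[str]]:
    if items is None:
        items = [c for c in data.columns if c not in RESERVED_COLS]
    return data[items].to_numpy(dtype=float), list(items)


@dataclass
class StabilityReport:
    """Bundle of bootstrap accuracy/stability outputs for one network."""

    items: list[str]
    edge_labels: list[tuple[str, str]]
    observed_edges: np.ndarray
    observed_strength: np.ndarray
    edge_ci: np.ndarray  # (E, 2) lower/upper
    boot_edges: np.ndarray = field(repr=False)  # (B_kept, E)
    boot_strength: np.ndarray = field(repr=False)  # (B_kept, p)
    edge_diff_sig: np.ndarray | None = None
    strength_diff_sig: np.ndarray | None = None
    drop_curve: pd.DataFrame | None = None
    cs_coefficient: float | None = None
    n_redrawn: int = 0
    n_dropped: int = 0

    def edge_ci_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_a": [a for a, _ in self.edge_labels],
                "node_b": [b for _, b in self.edge_labels],
                "estimate": self.observed_edges,
                "lower": self.edge_ci[:, 0],
                "upper": self.edge_ci[:, 1],
            }
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "items": self.items,
            "edge_ci": self.edge_ci_frame().to_dict(orient="list"),
            "cs_coefficient": self.cs_coefficient,
            "n_bootstrap_kept": int(self.boot_edges.shape[0]),
            "n_redrawn": self.n_redrawn,
            "n_dropped": self.n_dropped,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _bootstrap_arrays(
    X: np.ndarray,
    B: int,
    rng: np.random.Generator,
    gamma: float,
    n_lambda: int,
    ratio: float,
) -> tuple[np.ndarray, np.ndarray, int, int]:
    n, p = X.shape
    iu = np.triu_indices(p, k=1)
    edges = np.empty((B, iu[0].size))
    strengths = np.empty((B, p))
    redrawn = dropped = 0
    kept = 0
    for _ in range(B):
        Xb = None
        for attempt in range(_MAX_REDRAWS + 1):
            idx = rng.integers(0, n, n)
            cand = X[idx]
            if _resample_ok(cand):
                Xb = cand
                break
            redrawn += 1
        if Xb is None:
            dropped += 1
            continue
        W = _fast_weights(Xb, gamma, n_lambda, ratio)
        edges[kept] = W[iu]
        strengths[kept] = np.abs(W).sum(axis=0)
        kept += 1
    if dropped:
        warnings.warn(f"dropped {dropped} degenerate bootstrap replicates")
    return edges[:kept], strengths[:kept], redrawn, dropped


def edge_accuracy(
    data: pd.DataFrame,
    items: list[str] | None = None,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
) -> StabilityReport:
    """Nonparametric bootstrap CIs for every edge weight.

    ``B`` row-resamples with replacement, full re-estimation per resample,
    empirical (alpha/2, 1-alpha/2) quantiles per edge.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    X, items = _get_X(data, items)
    rng = np.random.default_rng(seed)
    W0 = _fast_weights(X, gamma, n_lambda, lambda_min_ratio)
    iu = np.triu_indices(len(items), k=1)
    boot_edges, boot_strength, redrawn, dropped = _bootstrap_arrays(
        X, B, rng, gamma, n_lambda, lambda_min_ratio
    )
    ci = np.quantile(boot_edges, [alpha / 2, 1 - alpha / 2], axis=0).T
    return StabilityReport(
        items=items,
        edge_labels=[(items[i], items[j]) for i, j in zip(*iu)],
        observed_edges=W0[iu],
        observed_strength=np.abs(W0).sum(axis=0),
        edge_ci=ci,
        boot_edges=boot_edges,
        boot_strength=boot_strength,
        n_redrawn=redrawn,
        n_dropped=dropped,
    )


def difference_tests(
    report: StabilityReport, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap difference tests between edge pairs and strength pairs.

    An off-diagonal entry is True when the (1-alpha) bootstrap CI of the
    pairwise difference excludes zero.  No multiplicity adjustment is
    applied.  The matrices are also stored on the report.
    """

    def sig_matrix(boot: np.ndarray) -> np.ndarray:
        k = boot.shape[1]
        sig = np.zeros((k, k), dtype=bool)
        for i in range(k):
            d = boot[:, i : i + 1] - boot  # (B, k)
            lo = np.quantile(d, alpha / 2, axis=0)
            hi = np.quantile(d, 1 - alpha / 2, axis=0)
            sig[i] = (lo > 0) | (hi < 0)
            sig[i, i] = False
        return sig

    report.edge_diff_sig = sig_matrix(report.boot_edges)
    report.strength_diff_sig = sig_matrix(report.boot_strength)
    return report.edge_diff_sig, report.strength_diff_sig


def case_dropping(
    data: pd.DataFrame,
    items: list[str] | None = None,
    drop_props: tuple[float, ...] = DEFAULT_DROP_GRID,
    B: int = 1000,
    seed: int | None = None,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
) -> pd.DataFrame:
    """Case-dropping bootstrap of strength centrality.

    For each drop proportion q, ``B`` subsamples of size round((1-q) n)
    without replacement are re-estimated and the Pearson correlation of
    the subsampled strength vector with the original recorded.  q = 0 is
    the identity subsample and records correlation exactly 1.
    """
    X, items = _get_X(data, items)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    s0 = np.abs(_fast_weights(X, gamma, n_lambda, lambda_min_ratio)).sum(axis=0)
    smallest = round((1 - max(drop_props)) * n)
    if smallest <= p + 10:
        raise ValueError(
            f"smallest retained subsample ({smallest}) must exceed p + 10 = {p + 10}"
        )
    rows = []
    for q in drop_props:
        if q == 0:
            rows += [(0.0, b, 1.0) for b in range(B)]
            continue
        m = round((1 - q) * n)
        for b in range(B):
            Xs = None
            for _ in range(_MAX_REDRAWS + 1):
                idx = rng.choice(n, m, replace=False)
                cand = X[idx]
                if _resample_ok(cand):
                    Xs = cand
                    break
            if Xs is None:
                rows.append((float(q), b, np.nan))
                continue
            s = np.abs(_fast_weights(Xs, gamma, n_lambda, lambda_min_ratio)).sum(axis=0)
            if s0.std() == 0 or s.std() == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(s0, s)[0, 1])
            rows.append((float(q), b, r))
    return pd.DataFrame(rows, columns=["proportion", "replicate", "correlation"])


def cs_coefficient(
    drop_curve: pd.DataFrame, r_threshold: float = 0.7, prob: float = 0.95
) -> float:
    """Correlation-stability coefficient from a case-dropping curve.

    The largest grid proportion q such that at every q' <= q the empirical
    (1 - prob) quantile of correlations is >= ``r_threshold`` (prefix rule,
    avoiding non-monotone artifacts); 0 if no proportion qualifies.
    Undefined correlations count as failures.
    """
    if drop_curve.empty:
        raise ValueError("drop_curve is empty")
    cs = 0.0
    for q, grp in drop_curve.groupby("proportion"):
        r = grp["correlation"].to_numpy(dtype=float)
        r = np.where(np.isnan(r), -1.0, r)  # undefined counts as failure
        if np.quantile(r, 1 - prob) >= r_threshold:
            cs = float(q)
        else:
            break
    return cs


def stability_report(
    data: pd.DataFrame,
    items: list[str] | None = None,
    B: int = 1000,
    alpha: float = 0.05,
    drop_props: tuple[float, ...] = DEFAULT_DROP_GRID,
    seed: int | None = None,
    **est_kwargs,
) -> StabilityReport:
    """Full report: edge CIs, difference tests, drop curve and CS."""
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    seed_edge, seed_drop = (int(s) for s in ss.generate_state(2) % (2**31))
    report = edge_accuracy(data, items, B=B, alpha=alpha, seed=seed_edge, **est_kwargs)
    difference_tests(report, alpha=alpha)
    report.drop_curve = case_dropping(
        data, items, drop_props=drop_props, B=B, seed=seed_drop, **est_kwargs
    )
    report.cs_coefficient = cs_coefficient(report.drop_curve)
    return report
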