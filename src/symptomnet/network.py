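"""Regularized partial-correlation network estimation.

The model object follows the fit/results idiom: construct a
:class:`GaussianGraphicalModel` from an item-response table, call
:meth:`~GaussianGraphicalModel.fit`, and receive a :class:`NetworkResults`
carrying the selected network (edge weights are regularized partial
correlations), the penalty chosen by EBIC, and centrality /
predictability / export methods.

Estimation pipeline: correlation matrix of the raw item scores (items
treated as continuous; Pearson by default, Spearman and two-step
polychoric available) -> graphical-lasso penalty path -> EBIC selection
-> partial correlations w_ij = -theta_ij / sqrt(theta_ii theta_jj).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import centrality as _centrality
from .glasso import glasso, glasso_path, partial_correlations

__all__ = [
    "GaussianGraphicalModel",
    "NetworkResults",
    "correlation_matrix",
    "estimate_network",
    "global_strength",
]

RESERVED_COLS = ("group", "sex")


def _item_matrix(data: pd.DataFrame, items: list[str]) -> np.ndarray:
    X = data[items].to_numpy(dtype=float)
    for j, it in enumerate(items):
        if X[:, j].std() == 0:
            raise ValueError(f"item {it!r} is constant; correlation undefined")
    return X


def _polychoric_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step polychoric correlation of two ordinal vectors.

    Thresholds come from the marginal cumulative proportions; the latent
    correlation then maximizes the bivariate-normal contingency likelihood
    (scalar optimization).
    """

    def cuts(v):
        cats, counts = np.unique(v, return_counts=True)
        cum = np.cumsum(counts)[:-1] / v.size
        return cats, stats.norm.ppf(cum)

    cx_cats, tx = cuts(x)
    cy_cats, ty = cuts(y)
    table = np.zeros((cx_cats.size, cy_cats.size))
    ix = np.searchsorted(cx_cats, x)
    iy = np.searchsorted(cy_cats, y)
    np.add.at(table, (ix, iy), 1.0)
    ex = np.concatenate([[-np.inf], tx, [np.inf]])
    ey = np.concatenate([[-np.inf], ty, [np.inf]])

    def negll(rho):
        cdf = np.zeros((ex.size, ey.size))
        dist = stats.multivariate_normal(cov=[[1.0, rho], [rho, 1.0]])
        for i in range(1, ex.size - 1):
            for j in range(1, ey.size - 1):
                cdf[i, j] = dist.cdf([ex[i], ey[j]])
        cdf[-1, :] = stats.norm.cdf(np.clip(ey, -38, 38))
        cdf[:, -1] = stats.norm.cdf(np.clip(ex, -38, 38))
        cdf[-1, -1] = 1.0
        cell = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
        return -np.sum(table * np.log(np.clip(cell, 1e-12, None)))

    res = optimize.minimize_scalar(negll, bounds=(-0.999, 0.999), method="bounded")
    return float(res.x)


def correlation_matrix(
    data: pd.DataFrame,
    items: list[str] | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Item correlation matrix (Pearson, Spearman or polychoric).

    Raises if any item is constant (its correlation is undefined) or if
    there are missing values.
    """
    if items is None:
        items = [c for c in data.columns if c not in RESERVED_COLS]
    if data[items].isna().any().any():
        raise ValueError("missing values in item columns")
    X = _item_matrix(data, items)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more rows than items")
    if method == "pearson":
        R = np.corrcoef(X, rowvar=False)
    elif method == "spearman":
        R = stats.spearmanr(X).statistic
        if np.isscalar(R):  # p == 2
            R = np.array([[1.0, R], [R, 1.0]])
    elif method == "polychoric":
        p = len(items)
        R = np.eye(p)
        for i in range(p):
            for j in range(i):
                R[i, j] = R[j, i] = _polychoric_pair(X[:, i], X[:, j])
        # nearest-PSD clip in case pairwise estimates are inconsistent
        w, V = np.linalg.eigh(R)
        if w.min() < 1e-10:
            R = (V * np.clip(w, 1e-10, None)) @ V.T
            d = np.sqrt(np.diag(R))
            R = R / np.outer(d, d)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=items, columns=items)


@dataclass
class NetworkResults:
    """Fitted symptom network.

    ``weights`` holds the regularized partial correlations (symmetric,
    zero diagonal); ``lambda_`` and ``gamma`` record the EBIC-selected
    penalty and hyperparameter; ``theta`` is the selected precision
    matrix.  Centrality and predictability are computed lazily from the
    stored weights and (for predictability) the training data.
    """

    items: list[str]
    communities: dict[str, str] | None
    weights: np.ndarray
    theta: np.ndarray
    corr: np.ndarray
    lambda_: float
    gamma: float
    n: int
    method: str
    model: "GaussianGraphicalModel | None" = field(default=None, repr=False)
    path_info: dict | None = field(default=None, repr=False)

    # -- basic graph quantities ------------------------------------------
    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(len(self.items), k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def edge_vector(self) -> np.ndarray:
        """Upper-triangle edge weights in row-major order."""
        iu = np.triu_indices(len(self.items), k=1)
        return self.weights[iu]

    def edges(self) -> pd.DataFrame:
        """Nonzero edges as a (node_a, node_b, weight) table."""
        rows = []
        p = len(self.items)
        for i in range(p):
            for j in range(i + 1, p):
                if self.weights[i, j] != 0.0:
                    rows.append(
                        {
                            "node_a": self.items[i],
                            "node_b": self.items[j],
                            "weight": self.weights[i, j],
                        }
                    )
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])

    def global_strength(self) -> float:
        """Sum of absolute edge weights over the upper triangle."""
        return float(np.abs(self.edge_vector()).sum())

    # -- centrality -------------------------------------------------------
    def strength(self) -> pd.DataFrame:
        return _centrality.strength(self.weights, self.items)

    def bridge_strength(self) -> pd.DataFrame:
        if self.communities is None:
            raise ValueError("bridge strength needs a community map")
        return _centrality.bridge_strength(self.weights, self.items, self.communities)

    def predictability(self) -> pd.Series:
        if self.model is None:
            raise ValueError("predictability needs the training data")
        return _centrality.predictability(self.model.data, self.items)

    def centrality_profile(self) -> pd.DataFrame:
        """Strength, bridge strength (if communities known), predictability."""
        out = self.strength()
        if self.communities is not None:
            out = out.join(self.bridge_strength())
        if self.model is not None:
            out["predictability"] = self.predictability()
        return out

    # -- presentation / export -------------------------------------------
    def summary(self) -> str:
        lines = [
            "Symptom network (EBIC graphical lasso)",
            f"  nodes: {len(self.items)}   edges: {self.n_edges}   n: {self.n}",
            f"  correlation: {self.method}   gamma: {self.gamma:g}   "
            f"lambda: {self.lambda_:.4f}",
            f"  global strength: {self.global_strength():.3f}",
            "",
            self.centrality_profile().round(3).to_string(),
        ]
        e = self.edges()
        if len(e):
            top = e.reindex(e["weight"].abs().sort_values(ascending=False).index)
            lines += ["", "Strongest edges:", top.head(5).round(3).to_string(index=False)]
        return "\n".join(lines)

    def adjacency_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.items, columns=self.items)

    def save(self, prefix: str | Path) -> None:
        """Write adjacency CSV, edge-list CSV and JSON metadata."""
        prefix = Path(prefix)
        self.adjacency_frame().to_csv(prefix.with_suffix(".adjacency.csv"))
        self.edges().to_csv(prefix.with_suffix(".edges.csv"), index=False)
        meta = {
            "items": self.items,
            "communities": self.communities,
            "lambda": self.lambda_,
            "gamma": self.gamma,
            "n": self.n,
            "method": self.method,
            "n_edges": self.n_edges,
            "global_strength": self.global_strength(),
        }
        prefix.with_suffix(".meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True)
        )


class GaussianGraphicalModel:
    """EBIC graphical-lasso network model of ordinal questionnaire items.

    Parameters
    ----------
    data : item-response table; item columns plus optional ``group`` /
        ``sex`` columns, which are ignored here.
    items : item columns to model (defaults to all non-reserved columns).
    communities : optional a-priori item -> community map used by bridge
        centrality downstream.
    method : correlation input; ``"pearson"`` (default, items treated as
        continuous), ``"spearman"`` or ``"polychoric"``.
    gamma : EBIC hyperparameter (0.5 is the field's standard).
    n_lambda, lambda_min_ratio : penalty path resolution.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        items: list[str] | None = None,
        communities: dict[str, str] | None = None,
        method: str = "pearson",
        gamma: float = 0.5,
        n_lambda: int = 100,
        lambda_min_ratio: float = 0.01,
    ):
        if items is None:
            items = [c for c in data.columns if c not in RESERVED_COLS]
        self.data = data
        self.items = list(items)
        self.communities = dict(communities) if communities else None
        self.method = method
        self.gamma = gamma
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "GaussianGraphicalModel":
        return cls(data, **kwargs)

    def fit(self, lam: float | None = None) -> NetworkResults:
        """Estimate the network; ``lam`` fixes the penalty, otherwise the
        EBIC minimum over the path is selected."""
        R = correlation_matrix(self.data, self.items, self.method)
        S = R.to_numpy()
        n = len(self.data)
        if lam is not None:
            theta = glasso(S, lam)
            info = None
            lam_sel = float(lam)
        else:
            res = glasso_path(
                S,
                n,
                gamma=self.gamma,
                n_lambda=self.n_lambda,
                lambda_min_ratio=self.lambda_min_ratio,
            )
            theta = res["theta"]
            lam_sel = res["lambda_"]
            info = {
                "lambdas": res["lambdas"],
                "ebic": res["ebic"],
                "edge_counts": res["edge_counts"],
            }
        return NetworkResults(
            items=self.items,
            communities=self.communities,
            weights=partial_correlations(theta),
            theta=theta,
            corr=S,
            lambda_=lam_sel,
            gamma=self.gamma,
            n=n,
            method=self.method,
            model=self,
            path_info=info,
        )


def estimate_network(
    data: pd.DataFrame,
    items: list[str] | None = None,
    communities: dict[str, str] | None = None,
    method: str = "pearson",
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    lam: float | None = None,
) -> NetworkResults:
    """Functional one-call wrapper around :class:`GaussianGraphicalModel`."""
    return GaussianGraphicalModel(
        data,
        items=items,
        communities=communities,
        method=method,
        gamma=gamma,
        n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio,
    ).fit(lam=lam)


def global_strength(net: NetworkResults) -> float:
    """Sum of absolute upper-triangle edge weights."""
    return net.global_strength()
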