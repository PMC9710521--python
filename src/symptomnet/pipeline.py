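"""End-to-end study pipeline.

Runs, in the order of the emulated study: item check (moments +
informativeness screen + scale reliability + group comparisons), network
estimation for the pooled sample and each group, centrality / bridge /
predictability, bootstrap stability for the group networks, the
permutation network comparison test (raw and covariate-adjusted), and the
random-subsample sensitivity analysis.  Everything is driven by one
:class:`PipelineConfig` and one integer seed; a rerun with the same config
writes a byte-identical summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparison import covariate_adjust, nct, network_correlation, subsample_sensitivity
from .descriptives import cronbach_alpha, group_t_tests, informativeness_screen, item_moments
from .network import estimate_network
from .simulate import COMMUNITIES, ITEM_RANGES
from .stability import DEFAULT_DROP_GRID, case_dropping, cs_coefficient, difference_tests, edge_accuracy

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("symptomnet")


@dataclass
class PipelineConfig:
    """Settings for one full pipeline run."""

    item_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(ITEM_RANGES)
    )
    communities: dict[str, str] = field(default_factory=lambda: dict(COMMUNITIES))
    group_col: str = "group"
    covariate: str | None = "sex"
    method: str = "pearson"
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    bootstrap_B: int = 1000
    drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID
    n_perm: int = 1000
    subsample_fraction: float = 0.3
    seed: int = 0
    output_dir: str = "symptomnet_output"

    @property
    def items(self) -> list[str]:
        return list(self.item_ranges)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        if "item_ranges" in raw:
            cfg.item_ranges = {k: tuple(v) for k, v in raw["item_ranges"].items()}
        if "drop_grid" in raw:
            cfg.drop_grid = tuple(raw["drop_grid"])
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["item_ranges"] = {k: list(v) for k, v in d["item_ranges"].items()}
        d["drop_grid"] = list(d["drop_grid"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    return obj


def _net_summary(net) -> dict:
    prof = net.centrality_profile()
    return {
        "n": net.n,
        "lambda": net.lambda_,
        "gamma": net.gamma,
        "n_edges": net.n_edges,
        "global_strength": net.global_strength(),
        "weights": net.weights,
        "centrality": {c: prof[c].to_dict() for c in prof.columns},
    }


def run_pipeline(config: PipelineConfig, data: pd.DataFrame) -> dict:
    """Run the full analysis and write the report bundle.

    Returns the summary dict (also written as ``summary.json``).  Any
    stage failure is re-raised with the stage name attached.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    items = config.items
    comm = config.communities
    seeds = {
        name: int(s)
        for name, s in zip(
            ["stab_a", "stab_b", "nct", "nct_adj", "sens"],
            np.random.SeedSequence(config.seed).generate_state(5) % (2**31),
        )
    }
    est = dict(
        gamma=config.gamma,
        n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
    )
    groups = sorted(pd.unique(data[config.group_col]).tolist())
    if len(groups) != 2:
        raise ValueError(f"expected 2 groups, found {groups}")
    ga, gb = groups
    parts = {
        "all": data,
        ga: data[data[config.group_col] == ga],
        gb: data[data[config.group_col] == gb],
    }
    settings = asdict(config)
    settings.pop("output_dir")  # environment detail, not part of the analysis
    summary: dict = {
        "schema_version": 1,
        "package_version": __version__,
        "settings": _jsonify({**settings, "groups": groups, "seeds": seeds}),
    }

    stage = "item check"
    try:
        moments = {name: item_moments(df, items) for name, df in parts.items()}
        excluded = informativeness_screen(moments["all"])
        scales: dict[str, list[str]] = {}
        for it, c in comm.items():
            scales.setdefault(c, []).append(it)
        alphas = {
            name: {c: cronbach_alpha(df, its) for c, its in scales.items() if len(its) > 1}
            for name, df in parts.items()
        }
        ttests = group_t_tests(data, items, config.group_col)
        summary["descriptives"] = _jsonify(
            {
                "moments": {k: v.to_dict() for k, v in moments.items()},
                "excluded_items": sorted(excluded),
                "cronbach_alpha": alphas,
                "t_tests": ttests.to_dict(),
            }
        )

        stage = "network estimation"
        use_items = [it for it in items if it not in excluded]
        nets = {
            name: estimate_network(df, items=use_items, communities=comm, method=config.method, **est)
            for name, df in parts.items()
        }
        summary["networks"] = _jsonify({k: _net_summary(v) for k, v in nets.items()})
        for name, net in nets.items():
            net.save(out / f"network_{name}")
            net.centrality_profile().to_csv(out / f"centrality_{name}.csv")

        # Table-1-style descriptives file with network-derived columns
        for name, df in parts.items():
            tab = moments[name].copy()
            tab["z_strength"] = nets[name].strength()["z_strength"]
            tab["predictability"] = nets[name].predictability()
            tab.to_csv(out / f"descriptives_{name}.csv")

        stage = "stability"
        summary["stability"] = {}
        for name, sd in ((ga, seeds["stab_a"]), (gb, seeds["stab_b"])):
            rep = edge_accuracy(
                parts[name], use_items, B=config.bootstrap_B, seed=sd, **est
            )
            difference_tests(rep)
            rep.drop_curve = case_dropping(
                parts[name], use_items, drop_props=config.drop_grid,
                B=config.bootstrap_B, seed=sd + 1, **est,
            )
            rep.cs_coefficient = cs_coefficient(rep.drop_curve)
            rep.to_json(out / f"stability_{name}.json")
            rep.edge_ci_frame().to_csv(out / f"edge_ci_{name}.csv", index=False)
            rep.drop_curve.to_csv(out / f"drop_curve_{name}.csv", index=False)
            summary["stability"][name] = _jsonify(
                {
                    "cs_coefficient": rep.cs_coefficient,
                    "median_ci_width": float(
                        np.median(rep.edge_ci[:, 1] - rep.edge_ci[:, 0])
                    ),
                    "n_dropped": rep.n_dropped,
                }
            )

        stage = "network comparison"
        res_nct = nct(
            parts[ga], parts[gb], items=use_items,
            n_perm=config.n_perm, seed=seeds["nct"], **est,
        )
        res_nct.to_json(out / "nct_groups.json")
        nct_block = {"groups": _nct_dict(res_nct)}
        if config.covariate is not None:
            adj = covariate_adjust(data, config.covariate, use_items)
            adj_parts = {g: adj[adj[config.group_col] == g] for g in (ga, gb)}
            res_adj = nct(
                adj_parts[ga], adj_parts[gb], items=use_items,
                n_perm=config.n_perm, seed=seeds["nct_adj"], **est,
            )
            res_adj.to_json(out / "nct_groups_adjusted.json")
            nct_block["groups_covariate_adjusted"] = _nct_dict(res_adj)
            net_adj = estimate_network(adj, items=use_items, communities=comm, **est)
            rho, p = network_correlation(nets["all"], net_adj)
            nct_block["covariate_network_spearman"] = {"rho": rho, "p": p}
        summary["nct"] = _jsonify(nct_block)

        stage = "sensitivity"
        sens = subsample_sensitivity(
            data, fraction=config.subsample_fraction, n_perm=config.n_perm,
            seed=seeds["sens"], items=use_items, **est,
        )
        sens["nct"].to_json(out / "nct_sensitivity.json")
        summary["sensitivity"] = _jsonify(
            {
                "fraction": sens["fraction"],
                "spearman_rho": sens["spearman_rho"],
                "spearman_p": sens["spearman_p"],
                "m_obs": sens["nct"].m_obs,
                "p_m": sens["nct"].p_m,
                "s_obs": sens["nct"].s_obs,
                "p_s": sens["nct"].p_s,
            }
        )
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise RuntimeError(f"pipeline failed during stage '{stage}': {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.info("pipeline complete: %s", out / "summary.json")
    return summary


def _nct_dict(r) -> dict:
    return {
        "m_obs": r.m_obs,
        "p_m": r.p_m,
        "s_obs": r.s_obs,
        "p_s": r.p_s,
        "group_global_strengths": list(r.group_global_strengths),
        "n_perm": r.n_perm,
    }
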