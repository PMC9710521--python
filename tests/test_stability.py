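"""Bootstrap machinery: edge CIs, difference tests, case dropping, CS.

Simulation-based checks run at reduced bootstrap counts and replicate
numbers relative to production defaults (B = 1000) to keep the suite
fast; the quantities checked are scale-free.
"""

import numpy as np
import pandas as pd
import pytest

import symptomnet as sn
from symptomnet.stability import (
    case_dropping,
    cs_coefficient,
    difference_tests,
    edge_accuracy,
)


def curve(points):
    """drop_curve frame from {proportion: [correlations]}."""
    rows = [(q, i, r) for q, rs in points.items() for i, r in enumerate(rs)]
    return pd.DataFrame(rows, columns=["proportion", "replicate", "correlation"])


class TestEdgeAccuracy:
    def test_determinism(self, junior_data):
        a = edge_accuracy(junior_data, B=100, seed=5)
        b = edge_accuracy(junior_data, B=100, seed=5)
        np.testing.assert_array_equal(a.edge_ci, b.edge_ci)
        np.testing.assert_array_equal(a.boot_edges, b.boot_edges)

    def test_cis_bracket_point_estimates(self, junior_data):
        rep = edge_accuracy(junior_data, B=200, seed=1)
        inside = (rep.edge_ci[:, 0] <= rep.observed_edges) & (
            rep.observed_edges <= rep.edge_ci[:, 1]
        )
        assert inside.mean() >= 0.95

    def test_large_n_concentration(self, junior_model):
        df = sn.sample(junior_model, 20_000, seed=2)
        rep = edge_accuracy(df, B=120, seed=3)
        top = np.argmax(np.abs(rep.observed_edges))
        assert rep.edge_ci[top, 1] - rep.edge_ci[top, 0] < 0.05

    def test_ci_width_shrinks_with_n(self, junior_model):
        widths = {}
        for n in (800, 4000):
            df = sn.sample(junior_model, n, seed=4)
            rep = edge_accuracy(df, B=150, seed=5)
            widths[n] = np.median(rep.edge_ci[:, 1] - rep.edge_ci[:, 0])
        assert widths[4000] < widths[800]

    def test_rejects_tiny_b(self, junior_data):
        with pytest.raises(ValueError, match="B must be"):
            edge_accuracy(junior_data, B=50)

    def test_coverage_of_strongest_edge(self, junior_model):
        """Percentile CIs are near-nominal for the same-n (shrunk) estimand;
        coverage of the unshrunk large-n value is systematically lower
        because the lasso biases the edge toward zero by an amount
        comparable to the CI width."""
        big = sn.sample(junior_model, 150_000, seed=77)
        net = sn.estimate_network(big)
        idx = {it: i for i, it in enumerate(net.items)}
        large_n_target = net.weights[idx["GAD1"], idx["GAD2"]]
        reps = 40
        ests, cis = [], []
        for r in range(reps):
            df = sn.sample(junior_model, 1000, seed=5000 + r)
            rep = edge_accuracy(df, B=300, seed=r)
            e = [
                k
                for k, (a, b) in enumerate(rep.edge_labels)
                if {a, b} == {"GAD1", "GAD2"}
            ][0]
            ests.append(rep.observed_edges[e])
            cis.append(rep.edge_ci[e])
        same_n_target = np.median(ests)
        cov_same_n = np.mean([lo <= same_n_target <= hi for lo, hi in cis])
        cov_large_n = np.mean([lo <= large_n_target <= hi for lo, hi in cis])
        assert 0.85 <= cov_same_n <= 0.99
        assert 0.5 <= cov_large_n < cov_same_n


class TestDifferenceTests:
    def test_edge_never_differs_from_itself(self, junior_data):
        rep = edge_accuracy(junior_data, B=120, seed=6)
        edge_sig, strength_sig = difference_tests(rep)
        assert not np.diag(edge_sig).any()
        assert not np.diag(strength_sig).any()
        assert edge_sig.shape == (21, 21)
        assert strength_sig.shape == (7, 7)

    @pytest.fixture(scope="class")
    def contrast_model(self):
        # one strong (0.45) and one weak (0.10) planted edge
        return sn.build_model(
            [("A", "B", 0.45), ("C", "D", 0.10)],
            {k: k for k in "ABCD"},
            {k: [0.0] for k in "ABCD"},
        )

    def test_power_for_planted_contrast(self, contrast_model):
        hits = 0
        reps = 15
        for r in range(reps):
            df = sn.sample(contrast_model, 5000, seed=200 + r)
            rep = edge_accuracy(df, items=list("ABCD"), B=250, seed=r)
            sig, _ = difference_tests(rep)
            lab = {fs: k for k, fs in enumerate(map(frozenset, rep.edge_labels))}
            i, j = lab[frozenset("AB")], lab[frozenset("CD")]
            hits += sig[i, j]
        assert hits >= 0.9 * reps

    def test_exchangeable_edges_rarely_differ(self):
        model = sn.build_model(
            [("A", "B", 0.3), ("C", "D", 0.3)],
            {k: k for k in "ABCD"},
            {k: [0.0] for k in "ABCD"},
        )
        false = 0
        reps = 15
        for r in range(reps):
            df = sn.sample(model, 3000, seed=400 + r)
            rep = edge_accuracy(df, items=list("ABCD"), B=250, seed=r)
            sig, _ = difference_tests(rep)
            lab = {fs: k for k, fs in enumerate(map(frozenset, rep.edge_labels))}
            false += sig[lab[frozenset("AB")], lab[frozenset("CD")]]
        assert false <= 0.2 * reps


class TestCaseDropping:
    def test_zero_drop_is_exactly_one(self, junior_data):
        out = case_dropping(junior_data, drop_props=(0.0, 0.3), B=25, seed=7)
        assert (out.loc[out["proportion"] == 0.0, "correlation"] == 1.0).all()

    def test_determinism(self, junior_data):
        a = case_dropping(junior_data, drop_props=(0.2, 0.5), B=30, seed=8)
        b = case_dropping(junior_data, drop_props=(0.2, 0.5), B=30, seed=8)
        assert a.equals(b)

    def test_minimum_subsample_guard(self, junior_model):
        tiny = sn.sample(junior_model, 40, seed=1)
        with pytest.raises(ValueError, match="retained subsample"):
            case_dropping(tiny, drop_props=(0.75,), B=10, seed=0)

    def test_strong_signal_stays_correlated(self, junior_model):
        df = sn.sample(junior_model, 10_000, seed=9)
        out = case_dropping(df, drop_props=(0.75,), B=60, seed=10)
        assert out["correlation"].median() > 0.9


class TestCSCoefficient:
    def test_perfect_curve_hits_grid_maximum(self):
        grid = np.round(np.arange(0.05, 0.76, 0.05), 2)
        c = curve({q: [1.0] * 30 for q in grid})
        assert cs_coefficient(c) == 0.75

    def test_failure_at_first_step_gives_zero(self):
        c = curve({0.05: [0.1] * 30, 0.1: [1.0] * 30})
        assert cs_coefficient(c) == 0.0

    def test_prefix_rule_blocks_recovery_after_dip(self):
        c = curve({0.05: [1.0] * 30, 0.1: [0.2] * 30, 0.15: [1.0] * 30})
        assert cs_coefficient(c) == 0.05

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        c = curve(
            {q: list(np.clip(rng.normal(0.9 - q, 0.1, 40), -1, 1))
             for q in (0.05, 0.25, 0.5, 0.75)}
        )
        values = [cs_coefficient(c, r_threshold=t) for t in (0.5, 0.7, 0.9)]
        assert values == sorted(values, reverse=True)

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            cs_coefficient(curve({}))
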