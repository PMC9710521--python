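"""Generator tests: copula construction, determinism, moment convergence,
and the two-group study preset's planted structure."""

import numpy as np
import pytest
from scipy import stats

import symptomnet as sn
from symptomnet.simulate import LatentNetworkModel, write_csv


def two_node_model(r, thresholds=(0.0,)):
    return sn.build_model(
        [("A", "B", r)] if r is not None else [],
        communities={"A": "X", "B": "Y"},
        thresholds={"A": np.array(thresholds), "B": np.array(thresholds)},
    )


class TestBuildModel:
    def test_empty_edge_spec_is_independence(self):
        m = sn.build_model(
            [], {"A": "X", "B": "Y"}, {"A": [0.5], "B": [0.5]}
        )
        np.testing.assert_array_equal(m.pcor, np.eye(2))
        np.testing.assert_allclose(m.latent_corr, np.eye(2))

    def test_two_node_partial_equals_marginal(self):
        m = two_node_model(0.5)
        assert m.latent_corr[0, 1] == pytest.approx(0.5)

    def test_three_node_chain_marginal_from_inversion(self):
        # A-B 0.6, B-C 0.6: frozen from direct inversion of the precision
        m = sn.build_model(
            [("A", "B", 0.6), ("B", "C", 0.6)],
            {"A": "X", "B": "Y", "C": "Z"},
            {k: [0.0] for k in "ABC"},
        )
        assert m.latent_corr[0, 2] == pytest.approx(0.5625)
        assert m.latent_corr[0, 1] == pytest.approx(0.75)

    def test_rejects_non_positive_definite(self):
        with pytest.raises(ValueError, match="eigenvalue"):
            sn.build_model(
                [("A", "B", 0.75), ("B", "C", 0.75)],
                {"A": "X", "B": "Y", "C": "Z"},
                {k: [0.0] for k in "ABC"},
            )

    def test_rejects_duplicate_edge(self):
        with pytest.raises(ValueError, match="duplicate"):
            sn.build_model(
                [("A", "B", 0.3), ("B", "A", 0.2)],
                {"A": "X", "B": "Y"},
                {"A": [0.0], "B": [0.0]},
            )

    def test_rejects_decreasing_thresholds(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            two_node_model(0.3, thresholds=(0.5, 0.2))

    def test_json_round_trip(self, tmp_path, junior_model):
        path = tmp_path / "model.json"
        junior_model.to_json(path)
        back = LatentNetworkModel.from_json(path)
        np.testing.assert_allclose(back.pcor, junior_model.pcor)
        assert back.items == junior_model.items
        assert back.communities == junior_model.communities


class TestSample:
    def test_degenerate_thresholds_give_constant_column(self):
        m = two_node_model(0.3, thresholds=(-8.0,))
        df = sn.sample(m, 500, seed=1)
        assert df["A"].nunique() == 1  # all mass above the only cut

    def test_same_seed_identical(self, junior_model):
        a = sn.sample(junior_model, 200, seed=9)
        b = sn.sample(junior_model, 200, seed=9)
        assert a.equals(b)

    def test_attenuated_correlation_matches_closed_form(self):
        # median split of a bivariate normal: phi coefficient = 2 arcsin(r)/pi
        m = two_node_model(0.5, thresholds=(0.0,))
        df = sn.sample(m, 20_000, seed=3)
        r = np.corrcoef(df["A"], df["B"])[0, 1]
        assert r == pytest.approx(2 * np.arcsin(0.5) / np.pi, abs=0.03)

    def test_moments_converge_to_closed_form(self, junior_model):
        df = sn.sample(junior_model, 50_000, seed=5)
        for item in sn.ITEMS:
            m, sd = junior_model.expected_moments(item)
            assert df[item].mean() == pytest.approx(m, abs=0.02)
            assert df[item].std(ddof=1) == pytest.approx(sd, abs=0.02)

    def test_identity_model_uncorrelated(self):
        m = sn.build_model(
            [],
            {k: k for k in "ABCD"},
            {k: [0.3] for k in "ABCD"},
        )
        df = sn.sample(m, 50_000, seed=6)
        R = np.corrcoef(df[list("ABCD")].to_numpy(float), rowvar=False)
        assert np.abs(R - np.eye(4)).max() < 0.03

    def test_values_within_declared_ranges(self, junior_data):
        for item, (lo, hi) in sn.ITEM_RANGES.items():
            assert junior_data[item].between(lo, hi).all()
        assert set(junior_data["sex"].unique()) <= {0, 1}


class TestStudyPreset:
    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            sn.study_preset("middle")

    def test_anxiety_pair_is_strongest_edge(self, junior_model, senior_model):
        for m in (junior_model, senior_model):
            off = np.abs(np.triu(m.pcor, 1))
            i, j = np.unravel_index(np.argmax(off), off.shape)
            assert {m.items[i], m.items[j]} == {"GAD1", "GAD2"}

    def test_within_edge_ordering(self, junior_model):
        idx = {it: i for i, it in enumerate(junior_model.items)}
        w = lambda a, b: abs(junior_model.pcor[idx[a], idx[b]])
        assert w("GAD1", "GAD2") > w("YSIS4", "YSIS5") > w("PHQ1", "PHQ2")

    def test_bridge_concentration(self, junior_model, senior_model):
        for m, hub in ((junior_model, "GAD1"), (senior_model, "PHQ2")):
            idx = {it: i for i, it in enumerate(m.items)}
            comm = [m.communities[it] for it in m.items]
            cross_total = 0.0
            hub_cross = 0.0
            for i in range(7):
                for j in range(i + 1, 7):
                    if comm[i] != comm[j] and m.pcor[i, j] != 0:
                        cross_total += abs(m.pcor[i, j])
                        if hub in (m.items[i], m.items[j]):
                            hub_cross += abs(m.pcor[i, j])
            assert hub_cross == cross_total > 0

    def test_senior_total_weight_exceeds_junior(self, junior_model, senior_model):
        tj = np.abs(np.triu(junior_model.pcor, 1)).sum()
        ts = np.abs(np.triu(senior_model.pcor, 1)).sum()
        assert ts > tj

    def test_senior_means_exceed_junior_and_sleep_ordering(
        self, junior_model, senior_model
    ):
        for item in sn.ITEMS:
            assert (
                senior_model.expected_moments(item)[0]
                > junior_model.expected_moments(item)[0]
            )
        means = {it: senior_model.expected_moments(it)[0] for it in sn.ITEMS}
        assert means["YSIS3"] > means["YSIS4"] > means["YSIS5"]

    def test_all_planted_edges_positive(self, junior_model, senior_model):
        for m in (junior_model, senior_model):
            off = np.triu(m.pcor, 1)
            assert np.all(off[off != 0] > 0)


class TestStudySimulation:
    def test_two_group_table_shape_and_labels(self):
        df = sn.simulate_study(300, 400, seed=11)
        assert len(df) == 700
        assert df["group"].value_counts()["junior"] == 300
        assert df["group"].value_counts()["senior"] == 400

    def test_csv_round_trip(self, tmp_path):
        df = sn.simulate_study(100, 100, seed=2)
        path = tmp_path / "responses.csv"
        write_csv(df, path)
        back = sn.read_responses(path)
        assert back.reset_index(drop=True).equals(df[back.columns])
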