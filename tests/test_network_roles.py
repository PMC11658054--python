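"""Contact networks, soft communities, bridging, relay flows and hierarchy."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from queenrelay.network_roles import (
    bridging_score,
    build_contact_network,
    build_relay_network,
    classify_task_group,
    coarse_grain_by_age,
    dominance_ranks,
    label_communities,
    soft_communities,
)

from conftest import make_contacts


class TestContactNetwork:
    def test_empty_day_empty_network(self):
        g = build_contact_network(make_contacts([]))
        assert g.number_of_nodes() == 0

    def test_edge_weight_counts_contacts(self):
        rows = [("a", "b", 10.0 * k, 10.0 * k + 1, 1.0, 0.0) for k in range(7)]
        rows.append(("b", "c", 100.0, 101.0, 1.0, 0.0))
        g = build_contact_network(make_contacts(rows))
        assert g["a"]["b"]["weight"] == 7
        assert g["b"]["c"]["weight"] == 1

    def test_total_weight_equals_contact_count(self, tiny_colony):
        g = build_contact_network(tiny_colony.contacts)
        total = sum(d["weight"] for _, _, d in g.edges(data=True))
        assert total == len(tiny_colony.contacts)


def planted_clique_graph(sizes=(8, 8, 8), inter=0, seed=0):
    g = nx.Graph()
    labels = {}
    node = 0
    for c, size in enumerate(sizes):
        members = list(range(node, node + size))
        node += size
        for a in members:
            labels[a] = c
            for b in members:
                if a < b:
                    g.add_edge(a, b, weight=10)
    if inter:
        rng = np.random.default_rng(seed)
        nodes = list(g.nodes)
        for _ in range(inter):
            a, b = rng.choice(nodes, 2, replace=False)
            if labels[a] != labels[b]:
                g.add_edge(a, b, weight=1)
    return g, labels


class TestSoftCommunities:
    def test_planted_cliques_recovered_above_95_percent(self):
        g, labels = planted_clique_graph()
        scores = soft_communities(g, k=3, seed=0)
        # map communities by majority assignment
        assign = scores.to_numpy().argmax(axis=1)
        for c in range(3):
            members = [n for n, lab in labels.items() if lab == c]
            cols = assign[[scores.index.get_loc(m) for m in members]]
            dominant = np.bincount(cols).argmax()
            vals = scores.iloc[[scores.index.get_loc(m) for m in members], dominant]
            assert (vals >= 0.95).all()

    def test_scores_row_sum_to_one(self, tiny_colony):
        g = build_contact_network(tiny_colony.contacts)
        # restrict to the giant component
        giant = max(nx.connected_components(g), key=len)
        scores = soft_communities(g.subgraph(giant), k=3, seed=1)
        assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-9)
        assert (scores.to_numpy() >= -1e-12).all()

    def test_bridge_node_splits_between_two_cliques(self):
        g, _ = planted_clique_graph(sizes=(6, 6))
        bridge = 99
        for n in range(6):
            g.add_edge(bridge, n, weight=5)
            g.add_edge(bridge, 6 + n, weight=5)
        scores = soft_communities(g, k=2, seed=0)
        b = scores.loc[bridge].to_numpy()
        assert abs(b[0] - b[1]) < 0.2

    def test_more_communities_than_nodes_rejected(self):
        g, _ = planted_clique_graph(sizes=(2,))
        with pytest.raises(ValueError):
            soft_communities(g, k=5)


class TestLabelling:
    def planted(self):
        scores = pd.DataFrame(
            {
                "c0": [0.9, 0.8, 0.1, 0.0, 0.1, 0.05],
                "c1": [0.05, 0.1, 0.8, 0.9, 0.1, 0.05],
                "c2": [0.05, 0.1, 0.1, 0.1, 0.8, 0.9],
            },
            index=["a1", "a2", "b1", "b2", "f1", "f2"],
        )
        ages = {"a1": 2, "a2": 3, "b1": 2, "b2": 4, "f1": 15, "f2": 18}
        patch = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        return scores, ages, patch

    def test_planted_labels_recovered(self):
        scores, ages, patch = self.planted()
        out = label_communities(scores, ages, patch_of=patch)
        assert out.loc["f1"].idxmax() == "F"
        assert out.loc["a1"].idxmax() == "N_A"
        assert out.loc["b2"].idxmax() == "N_B"

    def test_swapping_patches_swaps_nurse_labels_only(self):
        scores, ages, patch = self.planted()
        flipped = {b: ("B" if p == "A" else "A") for b, p in patch.items()}
        out1 = label_communities(scores, ages, patch_of=patch)
        out2 = label_communities(scores, ages, patch_of=flipped)
        pd.testing.assert_series_equal(out1["F"], out2["F"])
        pd.testing.assert_series_equal(out1["N_A"], out2["N_B"], check_names=False)

    def test_ambiguous_forager_without_tiebreak_raises(self):
        scores, ages, patch = self.planted()
        ages = {b: 5 for b in ages}
        with pytest.raises(ValueError):
            label_communities(scores, ages, patch_of=patch)

    def test_task_group_thresholds(self):
        labelled = pd.DataFrame(
            {
                "N_A": [0.5, 0.1, 0.3],
                "N_B": [0.3, 0.1, 0.35],
                "F": [0.2, 0.8, 0.35],
            },
            index=["nurse1", "forager1", "neither1"],
        )
        out = classify_task_group(labelled)
        assert out.loc["nurse1", "group"] == "nurse"
        assert out.loc["forager1", "group"] == "forager"
        assert out.loc["neither1", "group"] == "neither"


class TestBridgingScore:
    def test_equal_affiliations_give_one(self):
        assert np.isclose(bridging_score(1 / 3, 1 / 3), 1.0)

    def test_single_community_gives_zero(self):
        assert np.isclose(bridging_score(1.0, 0.0), 0.0)

    def test_p09_matches_binary_entropy(self):
        # H(0.9)/ln2 = -(0.9 ln 0.9 + 0.1 ln 0.1)/ln 2
        expected = -(0.9 * np.log(0.9) + 0.1 * np.log(0.1)) / np.log(2)
        assert np.isclose(bridging_score(0.9, 0.1), expected)
        assert np.isclose(expected, 0.4690, atol=5e-5)

    def test_zero_total_missing_and_negative_rejected(self):
        assert np.isnan(bridging_score(0.0, 0.0))
        with pytest.raises(ValueError):
            bridging_score(-0.1, 0.5)


class TestRelayNetwork:
    def test_flow_formula_single_event(self):
        g = build_relay_network({("A", "B"): 0.07})
        assert np.isclose(g["A"]["B"]["Q"], 0.07)

    def test_degrees_and_dk(self):
        g = build_relay_network(
            {("q", "a"): 1.0, ("q", "b"): 1.0, ("a", "b"): 0.5}
        )
        assert g.nodes["q"]["k_out"] == 2 and g.nodes["q"]["k_in"] == 0
        assert g.nodes["b"]["k_out"] == 0 and g.nodes["b"]["dk"] == -2

    def test_flow_totals_reconcile_with_engine_events(self, study_colony, scaled_params):
        from queenrelay.transmission_engine import run_ensemble

        sub = study_colony.contacts.head(3000)
        grid = np.array([2400.0])
        ens, all_events = run_ensemble(
            sub, study_colony.bees, scaled_params, grid=grid, collect_events=True
        )
        g = build_relay_network(ens.pair_flow)
        total_edges = sum(d["Q"] for _, _, d in g.edges(data=True))
        total_events = sum(
            ev["acquired_pg"] for events in all_events for ev in events
        ) / scaled_params.n_sims
        assert np.isclose(total_edges, total_events, rtol=1e-9)

    def test_direct_only_relay_is_queen_subgraph(self, study_colony, scaled_params):
        from queenrelay.transmission_engine import run_ensemble

        sub = study_colony.contacts.head(3000)
        queen_only = sub[(sub["i"] == "queen") | (sub["j"] == "queen")]
        grid = np.array([2400.0])
        full = run_ensemble(sub, study_colony.bees, scaled_params, grid=grid)
        direct = run_ensemble(queen_only, study_colony.bees, scaled_params, grid=grid)
        gd = build_relay_network(direct.pair_flow)
        gf = build_relay_network(full.pair_flow)
        for i, j in gd.edges:
            assert i == "queen"
            assert gf.has_edge(i, j)


class TestCohortFlow:
    def relay(self):
        return build_relay_network(
            {
                ("a1", "b1"): 3.0, ("b1", "a1"): 1.0,
                ("a1", "c1"): 2.0,
                ("b1", "c1"): 4.0, ("c1", "b1"): 4.0,
                ("queen", "a1"): 10.0,
            }
        )

    def ages(self):
        return {"a1": 4, "b1": 8, "c1": 12}

    def test_net_flows_match_hand_sums(self):
        gross, net = coarse_grain_by_age(self.relay(), self.ages(), pool_callows=False)
        net_map = {(r.cohort_a, r.cohort_b): r.net_pg for r in net.itertuples()}
        assert np.isclose(net_map[("4", "8")], 2.0)
        assert np.isclose(net_map[("4", "12")], 2.0)
        assert ("8", "12") not in net_map and ("12", "8") not in net_map

    def test_queen_excluded_from_cohorts(self):
        gross, _ = coarse_grain_by_age(self.relay(), self.ages())
        assert not (gross[["cohort_a", "cohort_b"]] == "queen").any().any()

    def test_callows_pooled(self):
        g = build_relay_network({("x", "y"): 1.0})
        gross, _ = coarse_grain_by_age(g, {"x": 1, "y": 5}, pool_callows=True)
        assert gross.iloc[0]["cohort_a"] == "0-2"


class TestDominance:
    def test_linear_chain_ranked_in_order(self):
        gross = pd.DataFrame(
            [
                {"cohort_a": "a", "cohort_b": "b", "flow_pg": 5.0},
                {"cohort_a": "b", "cohort_b": "c", "flow_pg": 5.0},
                {"cohort_a": "a", "cohort_b": "c", "flow_pg": 5.0},
            ]
        )
        ranks = dominance_ranks(gross)
        assert list(ranks["cohort"]) == ["a", "b", "c"]

    def test_symmetric_flows_equal_scores(self):
        gross = pd.DataFrame(
            [
                {"cohort_a": "a", "cohort_b": "b", "flow_pg": 2.0},
                {"cohort_a": "b", "cohort_b": "a", "flow_pg": 2.0},
            ]
        )
        ranks = dominance_ranks(gross)
        assert np.isclose(ranks["david_score"].iloc[0], ranks["david_score"].iloc[1])

    def test_three_cohort_matrix_matches_hand_davids_score(self):
        # P matrix from flows: a->b 3/4, a->c 1/2, b->c 1
        flows = pd.DataFrame(
            [
                {"cohort_a": "a", "cohort_b": "b", "flow_pg": 3.0},
                {"cohort_a": "b", "cohort_b": "a", "flow_pg": 1.0},
                {"cohort_a": "a", "cohort_b": "c", "flow_pg": 1.0},
                {"cohort_a": "c", "cohort_b": "a", "flow_pg": 1.0},
                {"cohort_a": "b", "cohort_b": "c", "flow_pg": 2.0},
            ]
        )
        P = {("a", "b"): 0.75, ("b", "a"): 0.25,
             ("a", "c"): 0.5, ("c", "a"): 0.5,
             ("b", "c"): 1.0, ("c", "b"): 0.0}
        w = {x: sum(v for (i, _), v in P.items() if i == x) for x in "abc"}
        l = {x: sum(v for (_, j), v in P.items() if j == x) for x in "abc"}
        w2 = {x: sum(v * w[j] for (i, j), v in P.items() if i == x) for x in "abc"}
        l2 = {x: sum(v * l[i] for (i, j), v in P.items() if j == x) for x in "abc"}
        expected = {x: w[x] + w2[x] - l[x] - l2[x] for x in "abc"}
        ranks = dominance_ranks(flows).set_index("cohort")
        for x in "abc":
            assert np.isclose(ranks.loc[x, "david_score"], expected[x])

    def test_single_cohort_rejected(self):
        with pytest.raises(ValueError):
            dominance_ranks(pd.DataFrame([{"cohort_a": "a", "cohort_b": "a",
                                           "flow_pg": 1.0}]))
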