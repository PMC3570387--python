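"""Family scorer, graph prior, hill-climbing search, bootstrap consensus."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from grnhub.netsearch import (
    FamilyScorer,
    FamilyScorerConfig,
    PriorHyperparameters,
    bootstrap_static_network,
    family_score,
    graph_log_prior,
    search_static_network,
)

LINEAR = FamilyScorerConfig(basis_type="linear")


def _panel(arrays: dict, n: int) -> pd.DataFrame:
    return pd.DataFrame(arrays, index=[f"s{i}" for i in range(n)]).T


def enumerate_dags(nodes):
    """All DAGs over labelled nodes (oracle; 25 for three nodes)."""
    pairs = [(a, b) for a in nodes for b in nodes if a != b]
    for keep in itertools.product([False, True], repeat=len(pairs)):
        edges = [p for p, k in zip(pairs, keep) if k]
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        if nx.is_directed_acyclic_graph(g):
            yield g


def total_posterior(graph, scorer, Z1, Z2, hyper):
    fam = sum(
        scorer.score(child, list(graph.predecessors(child)))
        for child in graph.nodes
    )
    return fam + graph_log_prior(graph, Z1, Z2, hyper)


class TestFamilyScore:
    def test_null_model_closed_form(self):
        rng = np.random.default_rng(0)
        data = _panel({"a": rng.normal(0, 1, 50), "b": rng.normal(0, 1, 50)}, 50)
        n = 50
        # standardized y has RSS = n - 1; BIC with one (variance) parameter
        expected = -0.5 * n * (np.log(2 * np.pi * (n - 1) / n) + 1) - 0.5 * np.log(n)
        assert family_score("a", [], data) == pytest.approx(expected)

    def test_nonlinear_signal_beats_null_by_wide_margin(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-3, 3, 200)
        y = np.sin(x) + rng.normal(0, 0.05, 200)
        data = _panel({"x": x, "y": y}, 200)
        gain = family_score("y", ["x"], data) - family_score("y", [], data)
        assert gain > 10

    def test_spline_captures_what_linear_cannot(self):
        # symmetric nonlinearity: linear fit is useless, spline is not
        rng = np.random.default_rng(2)
        x = rng.uniform(-2, 2, 300)
        y = x**2 + rng.normal(0, 0.1, 300)
        data = _panel({"x": x, "y": y}, 300)
        spline_gain = family_score("y", ["x"], data) - family_score("y", [], data)
        lin_gain = family_score("y", ["x"], data, LINEAR) - family_score(
            "y", [], data, LINEAR
        )
        assert spline_gain > 100 > lin_gain

    def test_noise_parent_lowers_penalized_score(self):
        """Adding an independent noise parent to the true parent set must
        lose to the true set for (nearly) every seed."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 200)
            y = 0.8 * x + rng.normal(0, 0.5, 200)
            z = rng.normal(0, 1, 200)
            data = _panel({"x": x, "y": y, "z": z}, 200)
            sc = FamilyScorer.from_panel(data)
            if sc.score("y", ["x"]) > sc.score("y", ["x", "z"]):
                wins += 1
        assert wins >= 18

    def test_deterministic_and_decomposable_caching(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(
            rng.normal(0, 1, (4, 60)), index=list("abcd")
        )
        sc = FamilyScorer.from_panel(data)
        assert sc.score("a", ["b", "c"]) == sc.score("a", ["c", "b"])

    def test_child_in_parent_set_rejected(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame(rng.normal(0, 1, (3, 30)), index=list("abc"))
        with pytest.raises(ValueError):
            FamilyScorer.from_panel(data).score("a", ["a", "b"])

    def test_small_sample_falls_back_to_linear(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame(rng.normal(0, 1, (5, 10)), index=list("abcde"))
        sc = FamilyScorer.from_panel(data)
        with pytest.warns(UserWarning, match="linear"):
            sc.score("a", ["b", "c"])


class TestGraphLogPrior:
    def _z(self, genes, entries):
        z = pd.DataFrame(0.0, index=genes, columns=genes)
        for (i, j), v in entries.items():
            z.at[i, j] = v
        return z

    def test_empty_graph_scores_zero(self):
        g = nx.DiGraph()
        g.add_nodes_from("ab")
        assert graph_log_prior(g, None, None) == 0.0

    def test_supported_edge_cancels_baseline_penalty(self):
        genes = list("ab")
        g = nx.DiGraph()
        g.add_nodes_from(genes)
        g.add_edge("a", "b")
        z1 = self._z(genes, {("a", "b"): 1.0})
        hyper = PriorHyperparameters(kappa=1.0, gamma1=1.0, gamma2=0.5)
        assert graph_log_prior(g, z1, None, hyper) == pytest.approx(0.0)

    def test_unsupported_edge_costs_kappa(self):
        g = nx.DiGraph()
        g.add_edge("a", "b")
        hyper = PriorHyperparameters(kappa=1.0)
        assert graph_log_prior(g, None, None, hyper) == pytest.approx(-1.0)

    def test_cyclic_graph_rejected(self):
        g = nx.DiGraph([("a", "b"), ("b", "a")])
        with pytest.raises(ValueError):
            graph_log_prior(g, None, None)


class TestSearchStaticNetwork:
    def test_matches_exhaustive_enumeration_on_three_genes(self):
        rng = np.random.default_rng(0)
        n = 60
        x = rng.normal(0, 1, n)
        y = 0.9 * x + rng.normal(0, 0.35, n)
        z = rng.normal(0, 1, n)
        data = _panel({"x": x, "y": y, "z": z}, n)
        hyper = PriorHyperparameters()
        scorer = FamilyScorer.from_panel(data, LINEAR)
        best_oracle = max(
            total_posterior(g, scorer, None, None, hyper)
            for g in enumerate_dags(list(data.index))
        )
        _graph, score = search_static_network(
            data, scorer_config=LINEAR, hyper=hyper, n_restarts=20, seed=0,
            return_score=True,
        )
        assert score == pytest.approx(best_oracle)

    def test_prior_rescues_edge_at_high_noise(self):
        """A supported Z1 edge is recovered at noise levels where the
        unsupported search misses it (paired over seeds)."""
        genes = ["x", "y", "z"]
        z1 = pd.DataFrame(0.0, index=genes, columns=genes)
        z1.at["x", "y"] = 1.0
        hyper = PriorHyperparameters(kappa=2.0, gamma1=4.0)
        with_prior = without_prior = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 40
            x = rng.normal(0, 1, n)
            y = 0.45 * x + rng.normal(0, 1.0, n)
            data = _panel({"x": x, "y": y, "z": rng.normal(0, 1, n)}, n)
            g_with = search_static_network(
                data, Z1=z1, scorer_config=LINEAR, hyper=hyper, seed=seed
            )
            g_wo = search_static_network(
                data, scorer_config=LINEAR, hyper=hyper, seed=seed
            )
            with_prior += ("x", "y") in g_with.edges()
            without_prior += ("x", "y") in g_wo.edges()
        assert with_prior > without_prior

    def test_pure_noise_large_kappa_gives_empty_graph(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(rng.normal(0, 1, (5, 40)), index=list("abcde"))
        g = search_static_network(
            data, scorer_config=LINEAR, hyper=PriorHyperparameters(kappa=10.0),
            seed=0,
        )
        assert g.number_of_edges() == 0

    def test_result_is_dag_and_respects_cap(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.normal(0, 1, (8, 50)), index=list("abcdefgh"))
        data.iloc[1] = 0.7 * data.iloc[0] + 0.3 * rng.normal(0, 1, 50)
        data.iloc[2] = -0.6 * data.iloc[1] + 0.4 * rng.normal(0, 1, 50)
        g = search_static_network(
            data, scorer_config=LINEAR, max_parents=2, n_restarts=3, seed=3
        )
        assert nx.is_directed_acyclic_graph(g)
        assert max(dict(g.in_degree()).values(), default=0) <= 2

    def test_posterior_decomposes_over_families(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame(rng.normal(0, 1, (4, 45)), index=list("abcd"))
        hyper = PriorHyperparameters()
        graph, score = search_static_network(
            data, scorer_config=LINEAR, hyper=hyper, seed=1, return_score=True
        )
        scorer = FamilyScorer.from_panel(data, LINEAR)
        assert score == pytest.approx(
            total_posterior(graph, scorer, None, None, hyper)
        )

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame(rng.normal(0, 1, (6, 35)), index=list("abcdef"))
        a = search_static_network(data, scorer_config=LINEAR, n_restarts=5, seed=9)
        b = search_static_network(data, scorer_config=LINEAR, n_restarts=5, seed=9)
        assert set(a.edges()) == set(b.edges())


class TestBootstrapStaticNetwork:
    def test_single_bootstrap_has_unit_frequencies(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.normal(0, 1, (4, 30)), index=list("abcd"))
        data.iloc[1] = 0.9 * data.iloc[0] + 0.1 * rng.normal(0, 1, 30)
        net = bootstrap_static_network(
            data, scorer_config=LINEAR, n_bootstraps=1, edge_freq_threshold=0.0,
            seed=0,
        )
        assert (net.edges["frequency"] == 1.0).all()

    def test_frequencies_are_multiples_of_inverse_bootstraps(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(rng.normal(0, 1, (4, 30)), index=list("abcd"))
        data.iloc[2] = 0.8 * data.iloc[3] + 0.2 * rng.normal(0, 1, 30)
        net = bootstrap_static_network(
            data, scorer_config=LINEAR, n_bootstraps=8, edge_freq_threshold=0.25,
            seed=1,
        )
        assert len(net.edges) > 0
        counts = net.edges["frequency"] * 8
        assert np.allclose(counts, counts.round())

    def test_sign_matches_full_panel_correlation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 40)
        data = _panel(
            {"x": x, "y": -0.9 * x + 0.1 * rng.normal(0, 1, 40)}, 40
        )
        net = bootstrap_static_network(
            data, scorer_config=LINEAR, n_bootstraps=5, edge_freq_threshold=0.2,
            seed=2,
        )
        assert len(net.edges) > 0
        assert (net.edges["sign"] == -1).all()

    def test_consensus_threshold_filters_edges(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.normal(0, 1, (5, 35)), index=list("abcde"))
        data.iloc[1] = 0.9 * data.iloc[0] + 0.1 * rng.normal(0, 1, 35)
        loose = bootstrap_static_network(
            data, scorer_config=LINEAR, n_bootstraps=10,
            edge_freq_threshold=0.1, seed=4,
        )
        tight = bootstrap_static_network(
            data, scorer_config=LINEAR, n_bootstraps=10,
            edge_freq_threshold=0.9, seed=4,
        )
        assert tight.edge_set() <= loose.edge_set()
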