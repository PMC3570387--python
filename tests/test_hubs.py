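"""Hub ranking, validation statistics, enrichment, evaluation."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from grnhub.containers import DisruptantPanel
from grnhub.hubs import (
    children_count_histogram,
    count_children,
    edge_recovery,
    hub_child_correlations,
    hub_recovery_rank,
    hub_subnetwork,
    hypergeometric_enrichment,
    predict_knockdown_direction,
    rank_hubs,
)


def _std_panel(values, genes, arrays, target_map=None):
    v = np.asarray(values, dtype=float)
    z = (v - v.mean(axis=0)) / v.std(axis=0, ddof=1)
    return DisruptantPanel(
        zvalues=pd.DataFrame(z, index=genes, columns=arrays),
        target_map=target_map or {},
    )


class TestCountChildren:
    def test_star_hub(self):
        g = nx.DiGraph([("H", f"c{i}") for i in range(10)])
        assert count_children(g)["H"] == 10

    def test_duplicate_edge_rows_count_once(self):
        counts = count_children([("H", "c"), ("H", "c"), ("H", "d")])
        assert counts["H"] == 2

    def test_leaf_gets_zero(self):
        g = nx.DiGraph([("a", "b")])
        assert count_children(g)["b"] == 0


class TestRankHubs:
    def test_min_rank_over_ties(self):
        g = nx.DiGraph()
        for i in range(5):
            g.add_edge("A", f"a{i}")
        for i in range(3):
            g.add_edge("B", f"b{i}")
            g.add_edge("C", f"c{i}")
        table = rank_hubs(g, top_k=3)
        ranks = dict(zip(table["gene"], table["rank"]))
        assert ranks == {"A": 1, "B": 2, "C": 2}

    def test_min_children_filter(self):
        g = nx.DiGraph([("A", f"a{i}") for i in range(25)] + [("B", "x")])
        table = rank_hubs(g, min_children=20)
        assert list(table["gene"]) == ["A"]

    def test_empty_network(self):
        assert len(rank_hubs(nx.DiGraph())) == 0

    def test_sorted_non_increasing(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(20, 0.2, directed=True, seed=1)
        g = nx.DiGraph((u, v) for u, v in g.edges() if u < v)
        table = rank_hubs(g, top_k=20)
        assert (np.diff(table["n_children"]) <= 0).all()


class TestHubSubnetwork:
    def test_star_subnetwork_is_whole_star(self):
        g = nx.DiGraph([("H", f"c{i}") for i in range(4)])
        sub = hub_subnetwork(g, "H")
        assert set(sub.edges()) == set(g.edges())

    def test_incident_edges_only(self):
        g = nx.DiGraph(
            [("p1", "H"), ("p2", "H"), ("H", "c1"), ("H", "c2"), ("H", "c3"),
             ("p1", "c1")]
        )
        sub = hub_subnetwork(g, "H")
        assert sub.number_of_edges() == 5
        assert ("p1", "c1") not in sub.edges()

    def test_unknown_gene_raises(self):
        with pytest.raises(KeyError, match="ghost"):
            hub_subnetwork(nx.DiGraph([("a", "b")]), "ghost")


def _panel_with_rows(rows: dict[str, list[float]], scale=0.05) -> DisruptantPanel:
    """Panel with standardized columns that embeds the prescribed rows
    (scaled by ``scale``; Pearson correlation is scale-invariant).  Four
    filler rows per column absorb the mean/variance constraints."""
    names = list(rows)
    R = np.asarray([rows[k] for k in names], dtype=float) * scale
    m = R.shape[1]
    fill = np.zeros((4, m))
    for j in range(m):
        s = R[:, j].sum()
        q = (R[:, j] ** 2).sum()
        # rows a,a,b,b with 2a+2b = -s and 2a^2+2b^2 = (n-1) - q, n = rows+4
        n = len(names) + 4
        half_sum = -s / 2
        half_sq = ((n - 1) - q) / 2
        disc = 2 * half_sq - half_sum**2
        assert disc > 0, "increase filler capacity or decrease scale"
        a = (half_sum + np.sqrt(disc)) / 2
        b = half_sum - a
        fill[:, j] = [a, a, b, b]
    values = np.vstack([R, fill])
    return DisruptantPanel(
        zvalues=pd.DataFrame(
            values,
            index=names + [f"fill{i}" for i in range(4)],
            columns=[f"a{j}" for j in range(m)],
        ),
        target_map={},
    )


class TestHubChildCorrelations:
    def test_identical_and_negated_rows(self):
        hub = [1.0, -2.0, 0.5, 1.5, -1.0]
        panel = _panel_with_rows(
            {"H": hub, "same": hub, "anti": [-v for v in hub]}
        )
        corrs = hub_child_correlations(panel, "H", ["same", "anti"])
        assert corrs["same"] == pytest.approx(1.0)
        assert corrs["anti"] == pytest.approx(-1.0)

    def test_hand_pearson(self):
        panel = _panel_with_rows(
            {"H": [1, 2, 3, 4], "double": [2, 4, 6, 8], "shuffled": [1, 3, 2, 4]}
        )
        corrs = hub_child_correlations(panel, "H", ["double", "shuffled"])
        assert corrs["double"] == pytest.approx(1.0)
        assert corrs["shuffled"] == pytest.approx(0.8)

    def test_matches_numpy_oracle_on_random_panel(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(6)]
        panel = _std_panel(rng.normal(0, 1, (6, 9)), genes,
                           [f"a{i}" for i in range(9)])
        corrs = hub_child_correlations(panel, "g0", genes[1:])
        z = panel.zvalues.to_numpy()
        for k, g in enumerate(genes[1:], start=1):
            assert corrs[g] == pytest.approx(np.corrcoef(z[0], z[k])[0, 1])

    def test_missing_gene_raises(self):
        rng = np.random.default_rng(1)
        panel = _std_panel(rng.normal(0, 1, (3, 4)), list("abc"),
                           [f"a{i}" for i in range(4)])
        with pytest.raises(KeyError):
            hub_child_correlations(panel, "a", ["zzz"])


class TestPredictKnockdownDirection:
    def test_sign_rule(self):
        preds = predict_knockdown_direction(
            {"pos": 0.8, "neg": -0.6, "none": 0.0, "undef": float("nan")}
        )
        assert preds == {"pos": "down", "neg": "up", "none": None, "undef": None}


class TestHypergeometricEnrichment:
    def test_exact_match_against_enumeration_oracle(self):
        """Exhaustive oracle: enumerate every possible query of the same
        size and count how many have at least the observed overlap."""
        universe = [f"u{i}" for i in range(20)]
        gene_set = set(universe[:5])
        query = set(universe[:4]) | {universe[10]}
        table = hypergeometric_enrichment(query, {"s": gene_set}, universe)
        observed = int(table.at[0, "overlap_count"])
        hits = total = 0
        for combo in itertools.combinations(universe, len(query)):
            total += 1
            hits += len(set(combo) & gene_set) >= observed
        assert table.at[0, "p_value"] == pytest.approx(hits / total, abs=1e-12)

    def test_full_overlap_probability(self):
        universe = [f"u{i}" for i in range(20)]
        s = set(universe[:5])
        table = hypergeometric_enrichment(s, {"s": s}, universe)
        assert table.at[0, "p_value"] == pytest.approx(1 / math.comb(20, 5))

    def test_zero_overlap_gives_p_one(self):
        universe = [f"u{i}" for i in range(10)]
        table = hypergeometric_enrichment(
            set(universe[:3]), {"s": set(universe[5:])}, universe
        )
        assert table.at[0, "p_value"] == 1.0

    def test_single_set_q_equals_p(self):
        universe = [f"u{i}" for i in range(12)]
        table = hypergeometric_enrichment(
            set(universe[:4]), {"s": set(universe[2:6])}, universe
        )
        assert table.at[0, "q_value"] == table.at[0, "p_value"]

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(set(), {"s": {"a"}}, set())

    def test_bh_qvalues_match_statsmodels_on_many_sets(self):
        rng = np.random.default_rng(0)
        universe = [f"u{i}" for i in range(30)]
        sets = {
            f"s{k}": set(rng.choice(universe, size=8, replace=False))
            for k in range(6)
        }
        query = set(universe[:10])
        table = hypergeometric_enrichment(query, sets, universe)
        assert ((table["q_value"] >= 0) & (table["q_value"] <= 1)).all()
        assert (table["overlap_count"] <= table["set_size"]).all()


class TestEdgeRecovery:
    def test_perfect_recovery(self):
        edges = {("a", "b"), ("b", "c")}
        assert edge_recovery(edges, edges) == (1.0, 1.0, 1.0)

    def test_empty_inferred_convention(self):
        assert edge_recovery(set(), {("a", "b")}) == (0.0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        truth = {(f"p{i}", f"c{i}") for i in range(10)}
        inferred = set(list(truth)[:6]) | {("x", "y"), ("y", "z")}
        p, r, f1 = edge_recovery(inferred, truth)
        assert (p, r) == (0.75, 0.6)
        assert f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)


class TestHubRecoveryRank:
    def test_ranks_and_sentinel(self):
        table = pd.DataFrame(
            {"gene": ["A", "B", "C"], "n_children": [5, 3, 3], "rank": [1, 2, 2]}
        )
        ranks = hub_recovery_rank(table, ["A", "C", "missing"])
        assert ranks["A"] == 1 and ranks["C"] == 2
        assert math.isinf(ranks["missing"])


def test_children_count_histogram():
    g = nx.DiGraph([("A", "x"), ("A", "y"), ("B", "x")])
    hist = children_count_histogram(g)
    got = dict(zip(hist["n_children"], hist["frequency"]))
    assert got == {0: 2, 1: 1, 2: 1}
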