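"""Hub identification, validation statistics and evaluation against truth.

Hubs are nodes with many distinct direct children in the consensus network;
they are candidate master regulators.  Validation logic mirrors the
siRNA-based follow-up: each child's correlation with the hub across the
knockdown panel predicts the direction of the child's change when the hub
is knocked down (positive correlation -> child goes down).
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .containers import ConsensusNetwork, DisruptantPanel


def _as_digraph(network) -> nx.DiGraph:
    if isinstance(network, ConsensusNetwork):
        return network.to_networkx()
    if isinstance(network, nx.DiGraph):
        return network
    # accept an iterable of (parent, child) pairs
    g = nx.DiGraph()
    g.add_edges_from(network)
    return g


def count_children(network) -> dict[str, int]:
    """Distinct direct children per node (duplicate edges count once)."""
    g = _as_digraph(network)
    return {node: g.out_degree(node) for node in g.nodes}


def rank_hubs(
    network,
    top_k: int = 50,
    min_children: int | None = None,
    descendants: bool = False,
) -> pd.DataFrame:
    """Rank genes by (distinct direct) children count.

    Returns a table (gene, n_children, rank) sorted non-increasing by count
    with lexicographic order within ties; tied genes share the minimum rank.
    ``descendants=True`` counts all downstream descendants instead of direct
    children.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    g = _as_digraph(network)
    if descendants:
        counts = {n: len(nx.descendants(g, n)) for n in g.nodes}
    else:
        counts = count_children(g)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    table = pd.DataFrame(rows, columns=["gene", "n_children"])
    if len(table):
        # min-rank over ties: rank of first row with that count
        table["rank"] = (
            table["n_children"].rank(method="min", ascending=False).astype(int)
        )
    else:
        table["rank"] = pd.Series(dtype=int)
    if min_children is not None:
        table = table[table["n_children"] >= min_children]
    return table.head(top_k).reset_index(drop=True)


def hub_subnetwork(network, gene: str) -> nx.DiGraph:
    """Subgraph of a hub, its parents and its children (incident edges only)."""
    g = _as_digraph(network)
    if gene not in g:
        raise KeyError(f"gene {gene!r} not in network")
    sub = nx.DiGraph()
    sub.add_node(gene)
    for p in g.predecessors(gene):
        sub.add_edge(p, gene, **g.edges[p, gene])
    for c in g.successors(gene):
        sub.add_edge(gene, c, **g.edges[gene, c])
    return sub


def hub_child_correlations(
    zpanel: DisruptantPanel,
    hub: str,
    children: list[str],
    method: str = "pearson",
) -> dict[str, float]:
    """Correlation of each child's z-row with the hub's across all arrays.

    Zero-variance rows yield NaN (undefined) rather than an exception.
    """
    z = zpanel.zvalues
    missing = [g for g in [hub, *children] if g not in z.index]
    if missing:
        raise KeyError(f"genes not in panel: {missing}")
    hub_row = z.loc[hub]
    out: dict[str, float] = {}
    for c in children:
        child_row = z.loc[c]
        if hub_row.std() == 0 or child_row.std() == 0:
            out[c] = float("nan")
        else:
            out[c] = float(hub_row.corr(child_row, method=method))
    return out


def predict_knockdown_direction(correlations: dict[str, float]) -> dict[str, str | None]:
    """Expected change of each child when the hub is knocked down.

    Positive hub-child correlation -> the child is predicted to go *down*
    with the hub; negative -> *up*; zero or undefined -> no call.
    """
    out: dict[str, str | None] = {}
    for child, r in correlations.items():
        if r is None or (isinstance(r, float) and (math.isnan(r) or r == 0)):
            out[child] = None
        else:
            out[child] = "down" if r > 0 else "up"
    return out


def hypergeometric_enrichment(
    query_genes,
    gene_sets: dict[str, set],
    universe,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query against gene sets.

    Gene sets are intersected with the universe; for each, the p-value is
    P(X >= overlap) drawing |query| genes from the universe, and q-values
    are Benjamini-Hochberg across sets.  Returns a table (gene_set_name,
    overlap_count, set_size, p_value, q_value) sorted by p-value.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query_genes)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    M, n_query = len(universe), len(query)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        overlap = len(members & query)
        # P(X >= overlap), X ~ Hypergeom(M, |set|, |query|)
        p = float(hypergeom.sf(overlap - 1, M, len(members), n_query))
        rows.append((name, overlap, len(members), min(p, 1.0)))
    table = pd.DataFrame(
        rows, columns=["gene_set_name", "overlap_count", "set_size", "p_value"]
    )
    if len(table):
        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    else:
        table["q_value"] = pd.Series(dtype=float)
    return table.sort_values("p_value", kind="stable").reset_index(drop=True)


def edge_recovery(inferred, truth) -> tuple[float, float, float]:
    """Directed-edge precision, recall and F1 of ``inferred`` against ``truth``.

    Both arguments are edge collections (sets of (parent, child) pairs, or
    anything :func:`count_children` accepts).  An empty inferred set scores
    (0, 0, 0) by convention.
    """
    inf_edges = set(_as_digraph(inferred).edges()) if not isinstance(inferred, set) else inferred
    true_edges = set(_as_digraph(truth).edges()) if not isinstance(truth, set) else truth
    tp = len(inf_edges & true_edges)
    precision = tp / len(inf_edges) if inf_edges else 0.0
    recall = tp / len(true_edges) if true_edges else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return precision, recall, f1


def hub_recovery_rank(hub_table: pd.DataFrame, planted_hubs: list[str]) -> dict[str, float]:
    """Rank of each planted hub in the children-count table (inf if absent)."""
    ranks = dict(zip(hub_table["gene"], hub_table["rank"]))
    return {h: float(ranks.get(h, math.inf)) for h in planted_hubs}


def children_count_histogram(network) -> pd.DataFrame:
    """Frequency table of children counts (n_children, frequency)."""
    counts = count_children(network)
    values = pd.Series(list(counts.values()), dtype=int)
    freq = values.value_counts().sort_index()
    return pd.DataFrame({"n_children": freq.index, "frequency": freq.to_numpy()})
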