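"""Plain-text readers and writers for the pipeline's exchange formats.

All formats are TSV: expression matrices (genes as rows, arrays as columns,
first column the gene identifier), same-shaped flag matrices with values in
{Good, Bad}, two-column target maps (array_id, target_gene), four-column
truth edge lists (parent, child, sign, weight) and consensus edge lists
(parent, child, frequency, sign).  Networks can also be exported as GraphML
for external viewers.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .containers import ConsensusNetwork, ExpressionMatrix, GroundTruthNetwork


def write_matrix(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", index_label="gene")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(matrix: ExpressionMatrix, values_path, flags_path=None) -> None:
    write_matrix(matrix.values, values_path)
    if flags_path is not None:
        if matrix.flags is None:
            raise ValueError("matrix has no flags to write")
        write_matrix(matrix.flags, flags_path)


def read_expression(values_path, flags_path=None) -> ExpressionMatrix:
    values = read_matrix(values_path)
    flags = read_matrix(flags_path) if flags_path is not None else None
    return ExpressionMatrix(values=values, flags=flags)


def write_target_map(target_map: dict[str, str], path) -> None:
    pd.DataFrame(
        sorted(target_map.items()), columns=["array_id", "target_gene"]
    ).to_csv(path, sep="\t", index=False)


def read_target_map(path) -> dict[str, str]:
    table = pd.read_csv(path, sep="\t")
    return dict(zip(table["array_id"], table["target_gene"]))


def write_truth_edges(truth: GroundTruthNetwork, path) -> None:
    rows = [
        (p, c, s, w) for (p, c), (s, w) in sorted(truth.edges.items())
    ]
    pd.DataFrame(rows, columns=["parent", "child", "sign", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_truth_edges(path, genes: list[str] | None = None) -> GroundTruthNetwork:
    table = pd.read_csv(path, sep="\t")
    edges = {
        (r.parent, r.child): (int(r.sign), float(r.weight))
        for r in table.itertuples(index=False)
    }
    if genes is None:
        genes = sorted({g for e in edges for g in e})
    return GroundTruthNetwork(genes=list(genes), edges=edges)


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def read_gene_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_consensus_edges(network: ConsensusNetwork, path) -> None:
    network.edges.to_csv(path, sep="\t", index=False)


def read_consensus_edges(path, genes: list[str], n_bootstraps: int) -> ConsensusNetwork:
    edges = pd.read_csv(path, sep="\t")
    return ConsensusNetwork(genes=list(genes), edges=edges, n_bootstraps=n_bootstraps)


def write_graphml(network, path) -> None:
    """GraphML export for external graph viewers."""
    g = network.to_networkx() if isinstance(network, ConsensusNetwork) else network
    nx.write_graphml(g, path)


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets in GMT format (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = {g for g in fields[2:] if g}
    return sets
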