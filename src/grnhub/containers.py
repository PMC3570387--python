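"""Shared data containers for the network-inference pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

DEFAULT_TIMEPOINTS = (0.0, 0.5, 1.5, 3.0, 6.0, 9.0, 12.0, 24.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions under which synthetic expression data are generated.

    Parameters
    ----------
    n_genes
        Number of genes in the simulated network (ignored by simulators,
        which take the gene list from the ground-truth network; kept for
        record-keeping).
    timepoints
        Sampling times in hours, strictly increasing.  Default is the
        eight-point post-stimulus design 0, 0.5, 1.5, 3, 6, 9, 12, 24 h.
    n_replicates
        Replicate time courses (default 3).
    noise_sd
        Standard deviation of i.i.d. Gaussian measurement noise on the
        log2 scale (added to the observed values, never propagated).
    intrinsic_sd
        Standard deviation of per-array intrinsic biological fluctuation
        of each gene's expression (log2 scale).  Unlike measurement noise,
        intrinsic fluctuations propagate along regulatory edges, so
        regulators and their targets co-vary across arrays — the signal
        that makes cross-panel correlation analysis informative.  Used by
        the knockdown-panel simulator.
    knockdown_factor
        Residual fraction of a targeted transcript after knockdown,
        in (0, 1]; default 0.2 (knockdown to <= 20% of baseline).
    decay
        Autoregressive persistence of each gene's deviation between
        consecutive timepoints.
    stimulus_strength
        Magnitude of the virtual stimulus root node's deviation at the
        first post-baseline timepoint.
    stimulus_decay
        Multiplicative decay of the stimulus deviation per subsequent
        timepoint: 1.0 (default) is a sustained step input, values < 1
        emulate the transient, wave-like transcriptional programs typical
        of acute stimuli (immediate-early genes spike and relax).
    seed
        Seed for all randomness in the generators.
    """

    n_genes: int = 50
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    n_replicates: int = 3
    noise_sd: float = 0.1
    intrinsic_sd: float = 0.8
    knockdown_factor: float = 0.2
    decay: float = 0.7
    stimulus_strength: float = 1.0
    stimulus_decay: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.timepoints)
        if len(tp) < 2:
            raise ValueError("need at least two timepoints")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing")
        object.__setattr__(self, "timepoints", tp)
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (0.0 < self.knockdown_factor <= 1.0):
            raise ValueError("knockdown_factor must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class GroundTruthNetwork:
    """A planted signed regulatory DAG with designated hub genes.

    ``edges`` maps ``(parent, child)`` to ``(sign, weight)`` with
    ``sign in {+1, -1}`` and ``weight > 0``.  ``hubs`` maps each designated
    hub gene to its prescribed number of direct children.
    """

    genes: list[str]
    edges: dict[tuple[str, str], tuple[int, float]]
    hubs: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        for (p, c) in self.edges:
            if p == c:
                raise ValueError(f"self-edge on {p!r}")
            if p not in gene_set or c not in gene_set:
                raise ValueError(f"edge ({p!r}, {c!r}) references unknown gene")
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ground-truth network must be acyclic")
        counts = self.children_counts()
        for hub, want in self.hubs.items():
            have = counts.get(hub, 0)
            if have != want:
                raise ValueError(
                    f"hub {hub!r} has {have} children, prescribed {want}"
                )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        for (p, c), (sign, weight) in self.edges.items():
            g.add_edge(p, c, sign=sign, weight=weight)
        return g

    def children_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {g: 0 for g in self.genes}
        for (p, _c) in self.edges:
            counts[p] += 1
        return counts

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def topological_order(self) -> list[str]:
        return list(nx.topological_sort(self.to_networkx()))


@dataclass
class TimecourseData:
    """Replicated time-course expression cube (genes x replicates x timepoints)."""

    cube: np.ndarray
    gene_ids: list[str]
    timepoints: tuple[float, ...]
    replicate_ids: list[str]

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=float)
        expected = (len(self.gene_ids), len(self.replicate_ids), len(self.timepoints))
        if self.cube.shape != expected:
            raise ValueError(
                f"cube shape {self.cube.shape} != genes x replicates x timepoints {expected}"
            )
        if len(self.timepoints) < 2:
            raise ValueError("need at least two timepoints")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_ids)

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a genes x arrays table with ``rep<k>_t<hours>`` columns."""
        cols = {}
        for r, rid in enumerate(self.replicate_ids):
            for t, tp in enumerate(self.timepoints):
                cols[f"{rid}_t{tp:g}"] = self.cube[:, r, t]
        return pd.DataFrame(cols, index=pd.Index(self.gene_ids, name="gene"))


@dataclass
class ZScoreCube:
    """Cross-gene z-scores of log-ratios to a reference timepoint.

    ``z`` has shape genes x replicates x timepoints; the reference slice is
    identically zero, and every other (replicate, timepoint) slice has mean 0
    and sample standard deviation 1 across genes.
    """

    z: np.ndarray
    gene_ids: list[str]
    timepoints: tuple[float, ...]
    replicate_ids: list[str]
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in ("first", "last"):
            raise ValueError("reference must be 'first' or 'last'")
        self.z = np.asarray(self.z, dtype=float)

    @property
    def reference_index(self) -> int:
        return 0 if self.reference == "first" else len(self.timepoints) - 1


@dataclass
class ExpressionMatrix:
    """Genes x arrays expression matrix (log2 scale) with optional quality flags.

    ``flags`` is a same-shaped categorical matrix whose entries are "Good"
    for probes that passed array QC.
    """

    values: pd.DataFrame
    flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene identifiers: {list(dupes)[:5]}")
        if self.flags is not None:
            if self.flags.shape != self.values.shape:
                raise ValueError("flags shape must match values shape")
            if not self.flags.index.equals(self.values.index) or not (
                self.flags.columns.equals(self.values.columns)
            ):
                raise ValueError("flags index/columns must match values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DisruptantPanel:
    """Within-array z-scores of log2 ratios versus a virtual median array.

    One column per knockdown array; ``target_map`` maps each array identifier
    to the gene targeted on that array.  Each column has mean 0 and sample
    standard deviation 1 across genes.
    """

    zvalues: pd.DataFrame
    target_map: dict[str, str]

    def __post_init__(self) -> None:
        cols = set(self.zvalues.columns)
        missing = [a for a in self.target_map if a not in cols]
        if missing:
            raise ValueError(f"target_map arrays not in panel: {missing}")
        z = self.zvalues.to_numpy()
        if z.shape[0] >= 2:
            mean = z.mean(axis=0)
            sd = z.std(axis=0, ddof=1)
            if np.abs(mean).max() > 1e-9 or np.abs(sd - 1.0).max() > 1e-9:
                raise ValueError("panel columns must be standardized (mean 0, sd 1)")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.zvalues.index)

    @property
    def targeted_genes(self) -> list[str]:
        return sorted(set(self.target_map.values()))


@dataclass
class EdgeConfidence:
    """Dense parent x child matrix of bootstrap edge probabilities.

    Entries are exact multiples of ``1 / n_bootstrap``; the diagonal is zero
    (no self-edges).
    """

    matrix: pd.DataFrame
    n_bootstrap: int
    provenance: str = "time_prior"

    def __post_init__(self) -> None:
        if self.provenance not in ("time_prior", "static_consensus"):
            raise ValueError("provenance must be 'time_prior' or 'static_consensus'")
        m = self.matrix.to_numpy()
        if (m < -1e-12).any() or (m > 1 + 1e-12).any():
            raise ValueError("confidences must lie in [0, 1]")
        if not self.matrix.index.equals(self.matrix.columns):
            raise ValueError("matrix must be square with identical row/column genes")
        if np.abs(np.diag(m)).max() > 0:
            raise ValueError("self-edge confidences must be zero")

    def threshold(self, p: float) -> pd.DataFrame:
        """Binary prior matrix keeping edges with confidence >= ``p``."""
        if not (0.0 < p <= 1.0):
            raise ValueError("threshold must be in (0, 1]")
        return (self.matrix >= p).astype(float)


@dataclass
class ConsensusNetwork:
    """Bootstrap consensus of static network searches.

    ``edges`` is a table with columns ``parent``, ``child``,
    ``frequency`` (fraction of bootstrap DAGs containing the edge) and
    ``sign`` (sign of the parent-child correlation over the full panel).
    """

    genes: list[str]
    edges: pd.DataFrame
    n_bootstraps: int

    def __post_init__(self) -> None:
        required = {"parent", "child", "frequency", "sign"}
        if not required.issubset(self.edges.columns):
            raise ValueError(f"edges table must have columns {sorted(required)}")
        if len(self.edges):
            f = self.edges["frequency"].to_numpy()
            if (f < 0).any() or (f > 1 + 1e-12).any():
                raise ValueError("edge frequencies must lie in [0, 1]")
            if (self.edges["parent"] == self.edges["child"]).any():
                raise ValueError("consensus network contains a self-edge")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.parent, row.child, frequency=row.frequency, sign=row.sign)
        return g

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["parent"], self.edges["child"]))
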