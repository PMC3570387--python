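"""Structure priors for static network inference.

Two priors are built ahead of the static search:

* the **time prior Z1** — a first-order dynamic network is fitted to many
  combinatorial resamples of the replicated time course; the bootstrap
  probability of each directed edge (its frequency over bootstrap networks)
  is thresholded (default 0.8) into a binary prior; and
* the **array prior Z2** — for each knockdown array, genes responding with
  a large within-array |z| become prior-supported children of the targeted
  gene, with the |z| as the prior weight and the z's sign retained for
  direction prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .containers import DisruptantPanel, EdgeConfidence, TimecourseData
from .netsearch import FamilyScorer, FamilyScorerConfig


@dataclass(frozen=True)
class BootstrapScheme:
    """Combinatorial resampling design for the dynamic-network bootstrap.

    With ``R`` replicates and ``T`` timepoints there are ``R**T`` possible
    combination time courses (choosing one replicate per timepoint); each
    bootstrap draws ``n_draws_per_bootstrap`` of them uniformly with
    replacement (default 25, i.e. ``T x 25`` arrays per bootstrap), and the
    whole procedure is repeated ``n_bootstraps`` times (default 100).
    """

    n_draws_per_bootstrap: int = 25
    n_bootstraps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws_per_bootstrap < 1:
            raise ValueError("n_draws_per_bootstrap must be >= 1")
        if self.n_bootstraps < 1:
            raise ValueError("n_bootstraps must be >= 1")

    def n_combinations(self, tc: TimecourseData) -> int:
        """Number of possible combination time courses, replicates**timepoints."""
        return tc.n_replicates ** tc.n_timepoints

    def n_arrays_per_bootstrap(self, tc: TimecourseData) -> int:
        """Arrays entering one bootstrap: timepoints x draws."""
        return tc.n_timepoints * self.n_draws_per_bootstrap


def resample_timecourses(
    tc: TimecourseData,
    n_draws: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw combination time courses: one replicate per timepoint, uniformly
    with replacement over the ``replicates**timepoints`` combination space.

    Returns an array of shape (n_draws, genes, timepoints).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    choice = rng.integers(0, tc.n_replicates, size=(n_draws, tc.n_timepoints))
    out = np.empty((n_draws, tc.n_genes, tc.n_timepoints))
    for d in range(n_draws):
        for t in range(tc.n_timepoints):
            out[d, :, t] = tc.cube[:, choice[d, t], t]
    return out


def fit_dynamic_network(
    series_set: np.ndarray,
    gene_ids: list[str],
    scorer_config: FamilyScorerConfig | None = None,
    max_parents: int = 3,
    allow_self_loops: bool = False,
) -> nx.DiGraph:
    """First-order stationary dynamic network over a set of time series.

    ``series_set`` has shape (series, genes, timepoints).  Transition pairs
    (x(t), x(t+1)) are pooled across series and timepoints; for each child
    gene, parents are chosen among all genes by greedy forward-backward
    selection of the penalized regression of child(t+1) on parents(t), up to
    ``max_parents``.  Time ordering resolves directionality, so no
    acyclicity constraint is applied.
    """
    if max_parents < 0:
        raise ValueError("max_parents must be >= 0")
    series_set = np.asarray(series_set, dtype=float)
    if series_set.ndim != 3:
        raise ValueError("series_set must be (series, genes, timepoints)")
    n_s, n_g, n_t = series_set.shape
    if n_t < 2:
        raise ValueError("each series needs at least 2 timepoints")
    if n_g != len(gene_ids):
        raise ValueError("gene_ids length must match the gene axis")

    # pooled lagged design: X rows are states at t, Y rows states at t+1
    X = series_set[:, :, :-1].transpose(0, 2, 1).reshape(n_s * (n_t - 1), n_g)
    Y = series_set[:, :, 1:].transpose(0, 2, 1).reshape(n_s * (n_t - 1), n_g)
    scorer = FamilyScorer(X, gene_ids, scorer_config, Y=Y)

    graph = nx.DiGraph()
    graph.add_nodes_from(gene_ids)
    for j in range(n_g):
        current: set[int] = set()
        best = scorer.score_idx(j, ())
        improved = True
        while improved:
            improved = False
            # forward step
            if len(current) < max_parents:
                gain, arg = 0.0, None
                for i in range(n_g):
                    if i in current or (i == j and not allow_self_loops):
                        continue
                    s = scorer.score_idx(j, tuple(sorted(current | {i})))
                    if s - best > max(gain, 1e-9):
                        gain, arg = s - best, i
                if arg is not None:
                    current.add(arg)
                    best += gain
                    improved = True
            # backward step
            gain, arg = 0.0, None
            for i in list(current):
                s = scorer.score_idx(j, tuple(sorted(current - {i})))
                if s - best > max(gain, 1e-9):
                    gain, arg = s - best, i
            if arg is not None:
                current.discard(arg)
                best += gain
                improved = True
        for i in current:
            graph.add_edge(gene_ids[i], gene_ids[j])
    return graph


def time_prior(
    tc: TimecourseData,
    scheme: BootstrapScheme | None = None,
    scorer_config: FamilyScorerConfig | None = None,
    max_parents: int = 3,
    threshold: float = 0.8,
    keep_graphs: bool = False,
):
    """Bootstrap dynamic-network edge confidences and the binary prior Z1.

    Runs :func:`fit_dynamic_network` on ``n_bootstraps`` independent
    combinatorial resamples of the time course; the bootstrap probability of
    edge i->j is the fraction of bootstrap networks containing it, and Z1
    keeps exactly the edges whose probability reaches ``threshold``.

    Returns ``(EdgeConfidence, Z1)``; with ``keep_graphs=True`` also the
    list of per-bootstrap graphs.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    scheme = scheme or BootstrapScheme()
    genes = list(tc.gene_ids)
    counts = pd.DataFrame(0.0, index=genes, columns=genes)
    graphs = []
    child_seeds = np.random.SeedSequence(scheme.seed).spawn(scheme.n_bootstraps)
    for ss in child_seeds:
        rng = np.random.default_rng(ss)
        series = resample_timecourses(tc, scheme.n_draws_per_bootstrap, rng)
        g = fit_dynamic_network(
            series, genes, scorer_config=scorer_config, max_parents=max_parents
        )
        for i, j in g.edges():
            counts.at[i, j] += 1
        if keep_graphs:
            graphs.append(g)
    conf = EdgeConfidence(
        matrix=counts / scheme.n_bootstraps,
        n_bootstrap=scheme.n_bootstraps,
        provenance="time_prior",
    )
    z1 = conf.threshold(threshold)
    if keep_graphs:
        return conf, z1, graphs
    return conf, z1


def array_prior(
    zpanel: DisruptantPanel,
    z_cutoff: float = 2.0,
    return_signs: bool = True,
):
    """Knockdown array prior Z2 and response signs.

    For each knockdown array targeting gene i, every other gene j with
    within-array |z_j| >= ``z_cutoff`` yields Z2[i, j] = |z_j| (else 0); the
    sign of z_j is stored separately for knockdown-direction prediction.
    Rows of untargeted genes are identically zero.  Raises if two arrays
    target the same gene (replicate handling is out of this prior's remit).
    """
    if z_cutoff < 0:
        raise ValueError("z_cutoff must be non-negative")
    genes = list(zpanel.zvalues.index)
    z2 = pd.DataFrame(0.0, index=genes, columns=genes)
    signs = pd.DataFrame(0, index=genes, columns=genes, dtype=int)
    seen: dict[str, str] = {}
    for array_id, target in zpanel.target_map.items():
        if target in seen:
            raise ValueError(
                f"duplicate arrays for target {target!r}: "
                f"{seen[target]!r} and {array_id!r}"
            )
        seen[target] = array_id
        if target not in z2.index:
            continue
        col = zpanel.zvalues[array_id]
        hit = col.abs() >= z_cutoff
        hit[target] = False  # no self-edge
        z2.loc[target, hit.index[hit]] = col[hit].abs().to_numpy()
        signs.loc[target, hit.index[hit]] = np.sign(col[hit]).astype(int).to_numpy()
    np.fill_diagonal(z2.values, 0.0)
    np.fill_diagonal(signs.values, 0)
    if return_signs:
        return z2, signs
    return z2
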