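"""Prior-guided static Bayesian-network structure search.

The posterior being maximised decomposes over child genes:

    score(G) = sum_child family_score(child, parents(child))
             + sum_edges [ -kappa + gamma1 * Z1[i,j] + gamma2 * Z2[i,j] ]

The family score is a penalized Gaussian additive-regression marginal
likelihood approximation: each child is regressed on its parents through a
B-spline (or linear) basis with a ridge penalty, and either a BIC or a
Laplace/evidence correction converts the fit into a model score.  The graph
prior rewards edges supported by the bootstrap dynamic-network time prior
(Z1, binary) and the knockdown array prior (Z2, |z|-weighted), and charges a
baseline penalty ``kappa`` per edge otherwise.

Search is greedy hill-climbing over single-edge additions, deletions and
reversals under an acyclicity constraint and an in-degree cap, with random
restarts; consensus networks come from bootstrap-resampling the arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .containers import ConsensusNetwork

_EPS_GAIN = 1e-9  # minimum score improvement for an accepted move


@dataclass(frozen=True)
class FamilyScorerConfig:
    """Configuration of the per-family regression score.

    basis_type
        "bspline" (cubic B-spline basis per parent, default) or "linear".
    n_basis
        Basis functions per parent for the B-spline basis (>= 4 for cubics).
    smoothness_penalty
        Ridge penalty lambda (> 0) on basis coefficients.
    approximation
        "bic" (default) or "laplace" marginal-likelihood approximation.
    """

    basis_type: str = "bspline"
    n_basis: int = 6
    smoothness_penalty: float = 1.0
    approximation: str = "bic"

    def __post_init__(self) -> None:
        if self.basis_type not in ("bspline", "linear"):
            raise ValueError("basis_type must be 'bspline' or 'linear'")
        if self.basis_type == "bspline" and self.n_basis < 4:
            raise ValueError("n_basis must be >= 4 for a cubic B-spline basis")
        if self.smoothness_penalty <= 0:
            raise ValueError("smoothness_penalty must be > 0")
        if self.approximation not in ("bic", "laplace"):
            raise ValueError("approximation must be 'bic' or 'laplace'")


@dataclass(frozen=True)
class PriorHyperparameters:
    """Edge-energy weights of the structure prior.

    Each edge contributes ``-kappa + gamma1 * Z1 + gamma2 * Z2`` to the log
    prior: ``kappa`` is the baseline cost of any edge, ``gamma1`` rewards
    edges in the thresholded time prior, ``gamma2`` scales the knockdown
    |z|-score reward.
    """

    kappa: float = 2.0
    gamma1: float = 2.0
    gamma2: float = 0.5

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.gamma1 < 0 or self.gamma2 < 0:
            raise ValueError("gamma1 and gamma2 must be non-negative")


def _standardize_columns(x: np.ndarray) -> np.ndarray:
    """Column z-scores (ddof=1); constant columns become all-zero."""
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    out = np.zeros_like(x)
    ok = sd > 0
    out[:, ok] = (x[:, ok] - mean[ok]) / sd[ok]
    return out


def _bspline_basis(x: np.ndarray, n_basis: int, degree: int = 3) -> np.ndarray:
    """Cubic B-spline design over ``x`` with interior knots at quantiles.

    Columns are centred so the basis is orthogonal to the intercept; a
    constant input yields an all-zero (informationless) design.
    """
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        return np.zeros((len(x), n_basis))
    n_interior = n_basis - degree - 1
    if n_interior > 0:
        qs = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
    else:
        interior = np.array([])
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    design = BSpline.design_matrix(
        np.clip(x, lo, hi), knots, degree, extrapolate=False
    ).toarray()
    return design - design.mean(axis=0)


class FamilyScorer:
    """Cached decomposable family scores over a fixed dataset.

    Precomputes the per-gene basis blocks and their Gram matrix once, so a
    single family evaluation reduces to solving a small ridge system — this
    is what makes bootstrap hill-climbing over thousands of candidate
    families tractable.

    ``X`` holds predictor samples (rows) by genes (columns); ``Y`` the
    responses, defaulting to ``X`` (the static case).  Columns are
    standardized internally; constant columns carry no signal.
    """

    def __init__(
        self,
        X: np.ndarray,
        var_names: list[str],
        config: FamilyScorerConfig | None = None,
        Y: np.ndarray | None = None,
    ) -> None:
        self.config = config or FamilyScorerConfig()
        self.names = list(var_names)
        self.index = {g: i for i, g in enumerate(self.names)}
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.names):
            raise ValueError("X must be samples x genes")
        self.n = X.shape[0]
        if self.n < 3:
            raise ValueError("need at least 3 samples")
        self.Xs = _standardize_columns(X)
        self.Ys = self.Xs if Y is None else _standardize_columns(np.asarray(Y, float))
        if self.Ys.shape != (self.n, len(self.names)):
            raise ValueError("Y must match X's samples and gene count")

        m = self.config.n_basis if self.config.basis_type == "bspline" else 1
        self._m = m
        if self.config.basis_type == "bspline":
            blocks = [
                _bspline_basis(self.Xs[:, g], m) for g in range(len(self.names))
            ]
            B = np.hstack(blocks)
        else:
            B = self.Xs
        self._gram = B.T @ B
        self._xty = B.T @ self.Ys
        # linear fallback for families too large for the sample size
        self._gram_lin = self.Xs.T @ self.Xs
        self._xty_lin = self.Xs.T @ self.Ys
        self._yty = (self.Ys**2).sum(axis=0)
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}
        self._warned_fallback = False

    # -- scoring -----------------------------------------------------------

    def score_idx(self, child: int, parents: tuple[int, ...]) -> float:
        """Score of ``child`` given the (sorted) tuple of parent indices."""
        key = (child, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        n, lam = self.n, self.config.smoothness_penalty
        yty = self._yty[child]
        if not parents:
            rss = yty
            eff_df = 0.0
            logdet_term = 0.0
        else:
            m = self._m
            use_linear = self.config.basis_type == "bspline" and (
                len(parents) * m + 1 >= n
            )
            if use_linear and not self._warned_fallback:
                warnings.warn(
                    "family larger than the sample size supports a B-spline "
                    "basis; falling back to a linear basis",
                    stacklevel=2,
                )
                self._warned_fallback = True
            if use_linear or self.config.basis_type == "linear":
                idx = np.asarray(parents)
                gram, xty = self._gram_lin, self._xty_lin
            else:
                idx = np.concatenate(
                    [np.arange(p * m, (p + 1) * m) for p in parents]
                )
                gram, xty = self._gram, self._xty
            gss = gram[np.ix_(idx, idx)]
            b = xty[idx, child]
            k = len(idx)
            a = gss + lam * np.eye(k)
            sol = np.linalg.solve(a, np.column_stack([b, np.eye(k)]))
            beta = sol[:, 0]
            a_inv = sol[:, 1:]
            rss = yty - b @ beta - lam * (beta @ beta)
            eff_df = k - lam * np.trace(a_inv)
            sign, logdet = np.linalg.slogdet(a)
            logdet_term = 0.5 * (k * np.log(lam) - logdet) if sign > 0 else -np.inf
        rss = max(rss, 1e-8 * max(yty, 1.0))
        loglik = -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)
        if self.config.approximation == "bic":
            score = loglik - 0.5 * (eff_df + 1.0) * np.log(n)
        else:  # laplace / ridge-evidence approximation
            score = loglik + logdet_term
        self._cache[key] = score
        return score

    def score(self, child: str, parent_set) -> float:
        """Score of a named child given a collection of named parents."""
        if child in parent_set:
            raise ValueError(f"parent set of {child!r} contains the child itself")
        ci = self.index[child]
        parents = tuple(sorted(self.index[p] for p in parent_set))
        return self.score_idx(ci, parents)

    @classmethod
    def from_panel(
        cls, data: pd.DataFrame, config: FamilyScorerConfig | None = None
    ) -> "FamilyScorer":
        """Scorer over a genes x arrays panel (arrays are the samples)."""
        return cls(data.to_numpy().T, list(data.index), config)


def family_score(
    child: str,
    parent_set,
    data: pd.DataFrame,
    scorer_config: FamilyScorerConfig | None = None,
) -> float:
    """One-off penalized family score of ``child`` given ``parent_set``.

    ``data`` is a genes x arrays panel.  For repeated scoring build a
    :class:`FamilyScorer` once instead.
    """
    return FamilyScorer.from_panel(data, scorer_config).score(child, parent_set)


# -- graph prior -----------------------------------------------------------


def _prior_matrix(
    genes: list[str],
    Z1: pd.DataFrame | None,
    Z2: pd.DataFrame | None,
    hyper: PriorHyperparameters,
) -> np.ndarray:
    """Per-edge log-prior contributions, aligned to ``genes`` order."""
    G = len(genes)
    prior = np.full((G, G), -float(hyper.kappa))
    if Z1 is not None:
        z1 = Z1.reindex(index=genes, columns=genes).fillna(0.0).to_numpy()
        prior += hyper.gamma1 * z1
    if Z2 is not None:
        z2 = Z2.reindex(index=genes, columns=genes).fillna(0.0).to_numpy()
        prior += hyper.gamma2 * z2
    np.fill_diagonal(prior, -np.inf)  # self-edges are never legal moves
    return prior


def graph_log_prior(
    graph: nx.DiGraph,
    Z1: pd.DataFrame | None,
    Z2: pd.DataFrame | None,
    hyper: PriorHyperparameters | None = None,
) -> float:
    """Edge-decomposable log prior: sum over edges of
    ``-kappa + gamma1 * Z1[i,j] + gamma2 * Z2[i,j]``; empty graph scores 0."""
    hyper = hyper or PriorHyperparameters()
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("graph must be a DAG")
    total = 0.0
    for i, j in graph.edges():
        term = -hyper.kappa
        if Z1 is not None and i in Z1.index and j in Z1.columns:
            term += hyper.gamma1 * float(Z1.at[i, j])
        if Z2 is not None and i in Z2.index and j in Z2.columns:
            term += hyper.gamma2 * float(Z2.at[i, j])
        total += term
    return total


# -- hill-climbing search --------------------------------------------------


def _reachable(children: list[set[int]], src: int, dst: int) -> bool:
    """True if ``dst`` is reachable from ``src`` along current edges."""
    if src == dst:
        return True
    seen = {src}
    stack = [src]
    while stack:
        node = stack.pop()
        for nxt in children[node]:
            if nxt == dst:
                return True
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return False


def _hill_climb(
    scorer: FamilyScorer,
    prior: np.ndarray,
    max_parents: int,
    init_edges: list[tuple[int, int]],
) -> tuple[dict[int, set[int]], float]:
    """Greedy add/delete/reverse search from ``init_edges`` to a local max.

    Returns the parent sets and the total posterior score.  Ties among
    equally improving moves break lexicographically by (move rank, parent,
    child) for determinism.
    """
    G = len(scorer.names)
    parents: list[set[int]] = [set() for _ in range(G)]
    children: list[set[int]] = [set() for _ in range(G)]
    for i, j in init_edges:
        parents[j].add(i)
        children[i].add(j)

    def fam(j: int) -> float:
        return scorer.score_idx(j, tuple(sorted(parents[j])))

    total = sum(fam(j) for j in range(G))
    total += sum(prior[i, j] for j in range(G) for i in parents[j])

    while True:
        moves: list[tuple[float, int, int, int]] = []  # delta, rank, i, j
        for j in range(G):
            base = fam(j)
            pj = parents[j]
            for i in pj:
                reduced = tuple(sorted(pj - {i}))
                d_del = scorer.score_idx(j, reduced) - base - prior[i, j]
                if d_del > _EPS_GAIN:
                    moves.append((d_del, 1, i, j))
                # reversal i->j  =>  j->i
                if len(parents[i]) < max_parents and np.isfinite(prior[j, i]):
                    grown = tuple(sorted(parents[i] | {j}))
                    d_rev = (
                        d_del
                        + scorer.score_idx(i, grown)
                        - fam(i)
                        + prior[j, i]
                    )
                    if d_rev > _EPS_GAIN:
                        moves.append((d_rev, 2, i, j))
            if len(pj) < max_parents:
                for i in range(G):
                    if i == j or i in pj or not np.isfinite(prior[i, j]):
                        continue
                    grown = tuple(sorted(pj | {i}))
                    d_add = scorer.score_idx(j, grown) - base + prior[i, j]
                    if d_add > _EPS_GAIN:
                        moves.append((d_add, 0, i, j))
        if not moves:
            break
        moves.sort(key=lambda m: (-m[0], m[1], m[2], m[3]))
        applied = False
        for delta, rank, i, j in moves:
            if rank == 0:  # add i -> j
                if _reachable(children, j, i):
                    continue
                parents[j].add(i)
                children[i].add(j)
            elif rank == 1:  # delete i -> j
                parents[j].discard(i)
                children[i].discard(j)
            else:  # reverse i -> j
                parents[j].discard(i)
                children[i].discard(j)
                if _reachable(children, i, j):
                    parents[j].add(i)
                    children[i].add(j)
                    continue
                parents[i].add(j)
                children[j].add(i)
            total += delta
            applied = True
            break
        if not applied:
            break

    return {j: parents[j] for j in range(G)}, total


def _random_init_edges(
    G: int, max_parents: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """A random DAG seeded along a random topological order."""
    perm = rng.permutation(G)
    n_edges = int(rng.integers(0, max(G, 2)))
    edges: set[tuple[int, int]] = set()
    indeg = np.zeros(G, dtype=int)
    for _ in range(n_edges):
        a, b = rng.integers(0, G, size=2)
        if a == b:
            continue
        lo, hi = (a, b) if np.flatnonzero(perm == a)[0] < np.flatnonzero(perm == b)[0] else (b, a)
        if indeg[hi] >= max_parents or (lo, hi) in edges:
            continue
        edges.add((int(lo), int(hi)))
        indeg[hi] += 1
    return sorted(edges)


def search_static_network(
    data: pd.DataFrame,
    Z1: pd.DataFrame | None = None,
    Z2: pd.DataFrame | None = None,
    scorer_config: FamilyScorerConfig | None = None,
    hyper: PriorHyperparameters | None = None,
    max_parents: int = 3,
    n_restarts: int = 1,
    seed: int = 0,
    scorer: FamilyScorer | None = None,
    return_score: bool = False,
):
    """Hill-climb a DAG maximising family scores plus the edge prior.

    ``data`` is a genes x arrays panel (each array one sample).  The first
    restart starts from the empty graph; subsequent restarts start from
    random DAGs.  Deterministic for a fixed seed; the returned score is
    never below the empty graph's.
    """
    if max_parents < 1:
        raise ValueError("max_parents must be >= 1")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    genes = list(data.index)
    if scorer is None:
        scorer = FamilyScorer.from_panel(data, scorer_config)
    hyper = hyper or PriorHyperparameters()
    prior = _prior_matrix(genes, Z1, Z2, hyper)
    rng = np.random.default_rng(seed)

    best_parents: dict[int, set[int]] | None = None
    best_total = -np.inf
    for r in range(n_restarts):
        init = [] if r == 0 else _random_init_edges(len(genes), max_parents, rng)
        parents, total = _hill_climb(scorer, prior, max_parents, init)
        if total > best_total + _EPS_GAIN:
            best_total = total
            best_parents = parents

    graph = nx.DiGraph()
    graph.add_nodes_from(genes)
    assert best_parents is not None
    for j, pj in best_parents.items():
        for i in pj:
            graph.add_edge(genes[i], genes[j])
    if return_score:
        return graph, best_total
    return graph


def bootstrap_static_network(
    data: pd.DataFrame,
    Z1: pd.DataFrame | None = None,
    Z2: pd.DataFrame | None = None,
    scorer_config: FamilyScorerConfig | None = None,
    hyper: PriorHyperparameters | None = None,
    max_parents: int = 3,
    n_bootstraps: int = 100,
    edge_freq_threshold: float = 0.5,
    n_restarts: int = 1,
    seed: int = 0,
) -> ConsensusNetwork:
    """Consensus network over bootstrap resamples of the arrays.

    Each bootstrap resamples the panel's arrays (columns) with replacement
    to the original count, reruns the structure search, and the consensus
    keeps edges whose frequency across bootstrap DAGs reaches
    ``edge_freq_threshold``.  Edge signs are the sign of the parent-child
    Pearson correlation over the *full* (unresampled) panel.
    """
    if n_bootstraps < 1:
        raise ValueError("n_bootstraps must be >= 1")
    genes = list(data.index)
    n_arrays = data.shape[1]
    counts: dict[tuple[str, str], int] = {}
    children_seeds = np.random.SeedSequence(seed).spawn(n_bootstraps)
    for ss in children_seeds:
        rng = np.random.default_rng(ss)
        cols = rng.integers(0, n_arrays, size=n_arrays)
        boot = data.iloc[:, cols]
        boot.columns = [f"b{k}" for k in range(n_arrays)]
        graph = search_static_network(
            boot,
            Z1=Z1,
            Z2=Z2,
            scorer_config=scorer_config,
            hyper=hyper,
            max_parents=max_parents,
            n_restarts=n_restarts,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for e in graph.edges():
            counts[e] = counts.get(e, 0) + 1

    full = data.to_numpy()
    gi = {g: k for k, g in enumerate(genes)}
    rows = []
    for (p, c), n_hits in sorted(counts.items()):
        freq = n_hits / n_bootstraps
        if freq < edge_freq_threshold:
            continue
        x, y = full[gi[p]], full[gi[c]]
        if x.std() == 0 or y.std() == 0:
            sign = 0
        else:
            sign = int(np.sign(np.corrcoef(x, y)[0, 1]))
        rows.append((p, c, freq, sign))
    edges = pd.DataFrame(rows, columns=["parent", "child", "frequency", "sign"])
    edges = edges.sort_values(
        ["frequency", "parent", "child"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return ConsensusNetwork(genes=genes, edges=edges, n_bootstraps=n_bootstraps)
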