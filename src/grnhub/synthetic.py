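"""Ground-truth networks and synthetic time-course / knockdown-panel data.

The generator plants a known signed DAG and simulates the two kinds of data
the inference pipeline consumes:

* a replicated time course in which a virtual stimulus root node ("SFD",
  for survival-factor deprivation) perturbs designated response genes and
  the perturbation propagates down the network with linear-Gaussian
  first-order dynamics; and
* a knockdown ("disruptant") panel with one array per targeted gene, in
  which the target drops to ``knockdown_factor`` of baseline and the effect
  propagates to descendants with the same signed linear rule.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .containers import GroundTruthNetwork, SimulationConfig, TimecourseData

STIMULUS_NODE = "SFD"


class ConfigurationError(ValueError):
    """An infeasible generator configuration (e.g. a hub that cannot be wired)."""


def _gene_names(n: int, reserved: list[str]) -> list[str]:
    """``reserved`` hub names first, then filler genes g01, g02, ..."""
    width = max(2, len(str(n)))
    fillers = []
    k = 1
    while len(reserved) + len(fillers) < n:
        name = f"g{k:0{width}d}"
        if name not in reserved:
            fillers.append(name)
        k += 1
    return list(reserved) + fillers


def _draw_sign_weight(
    rng: np.random.Generator, n: int, negative_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    signs = np.where(rng.random(n) < negative_fraction, -1, 1)
    weights = rng.uniform(0.7, 1.3, size=n)
    return signs, weights


def make_ground_truth(
    n_genes: int,
    hub_spec: list[tuple[str, int]],
    edge_sign_fraction: float = 0.25,
    extra_edge_count: int = 0,
    seed: int = 0,
) -> GroundTruthNetwork:
    """Build a planted DAG in which each designated hub has exactly its
    prescribed number of distinct direct children.

    Hubs are placed first in a fixed topological order, so hub ``k`` can be
    wired to any of the ``n_genes - 1 - k`` genes after it.  ``extra_edge_count``
    additional edges are sampled among non-hub parents, respecting the
    topological order (hence acyclicity) and never duplicating an edge.
    A fraction ``edge_sign_fraction`` of all edges is negative.

    Raises
    ------
    ConfigurationError
        If a hub's prescribed children count cannot be realised.
    """
    rng = np.random.default_rng(seed)
    hub_ids = [h for h, _ in hub_spec]
    if len(set(hub_ids)) != len(hub_ids):
        raise ConfigurationError("duplicate hub identifiers in hub_spec")
    if len(hub_ids) > n_genes:
        raise ConfigurationError("more hubs than genes")
    genes = _gene_names(n_genes, hub_ids)
    order = {g: i for i, g in enumerate(genes)}

    edges: dict[tuple[str, str], tuple[int, float]] = {}
    for k, (hub, n_children) in enumerate(hub_spec):
        downstream = genes[k + 1 :]
        if n_children >= n_genes or n_children > len(downstream):
            raise ConfigurationError(
                f"hub {hub!r}: cannot place {n_children} children "
                f"({len(downstream)} genes available downstream)"
            )
        children = rng.choice(downstream, size=n_children, replace=False)
        signs, weights = _draw_sign_weight(rng, n_children, edge_sign_fraction)
        for c, s, w in zip(children, signs, weights):
            edges[(hub, str(c))] = (int(s), float(w))

    # Extra edges: non-hub parents only, so hub children counts stay exact.
    non_hub = [g for g in genes if g not in set(hub_ids)]
    candidates = [
        (p, c)
        for p in non_hub
        for c in genes
        if order[c] > order[p] and (p, c) not in edges
    ]
    if extra_edge_count > len(candidates):
        raise ConfigurationError(
            f"extra_edge_count {extra_edge_count} exceeds the "
            f"{len(candidates)} available non-hub edge slots"
        )
    if extra_edge_count:
        idx = rng.choice(len(candidates), size=extra_edge_count, replace=False)
        signs, weights = _draw_sign_weight(rng, extra_edge_count, edge_sign_fraction)
        for i, s, w in zip(idx, signs, weights):
            edges[candidates[i]] = (int(s), float(w))

    return GroundTruthNetwork(genes=genes, edges=edges, hubs=dict(hub_spec))


def make_cascade_ground_truth(
    n_genes: int = 50,
    layer_sizes: tuple[int, ...] = (4, 3, 3, 3, 3, 4),
    layer_scales: tuple[float, ...] | None = None,
    edge_sign_fraction: float = 0.25,
    weight_jitter: float = 0.03,
    seed: int = 0,
) -> tuple[GroundTruthNetwork, list[str]]:
    """Build a layered cascade for stimulus-response simulations.

    Layer 1 genes are direct stimulus targets; each gene in layer ``k > 1``
    has exactly one parent drawn from layer ``k - 1``, so a (transient)
    stimulus travels down the cascade as a wave: each layer peaks a step
    after its parent layer, and layers take turns dominating the cross-gene
    expression spread.  This staggering is what lets a cross-gene z-score
    criterion catch every layer in some window of adjacent timepoints even
    though no single timepoint can show many genes at |z| >= 2
    simultaneously.  Remaining genes are unconnected bystanders.

    ``layer_scales`` sets the target amplitude of each layer relative to
    the stimulus; the edge weight into layer ``k`` is
    ``|scales[k] / scales[k-1]|`` (uniformly jittered by ``weight_jitter``),
    keeping within-layer amplitudes nearly homogeneous so a whole layer
    clears a selection threshold together.  Default scales are 1 for every
    layer.

    Returns the network and the list of stimulus-target genes (layer 1).
    """
    rng = np.random.default_rng(seed)
    total = sum(layer_sizes)
    if total > n_genes:
        raise ConfigurationError(
            f"layer_sizes sum to {total} but only {n_genes} genes requested"
        )
    if layer_scales is None:
        layer_scales = tuple(1.0 for _ in layer_sizes)
    if len(layer_scales) != len(layer_sizes) or any(s <= 0 for s in layer_scales):
        raise ConfigurationError("layer_scales must be positive, one per layer")
    genes = _gene_names(n_genes, [])
    layers: list[list[str]] = []
    pos = 0
    for size in layer_sizes:
        layers.append(genes[pos : pos + size])
        pos += size

    edges: dict[tuple[str, str], tuple[int, float]] = {}
    for k, (prev, cur) in enumerate(zip(layers, layers[1:]), start=1):
        parents = rng.choice(prev, size=len(cur), replace=True)
        base_w = layer_scales[k] / layer_scales[k - 1]
        for child, parent in zip(cur, parents):
            sign = -1 if rng.random() < edge_sign_fraction else 1
            w = base_w * rng.uniform(1.0 - weight_jitter, 1.0 + weight_jitter)
            edges[(str(parent), child)] = (int(sign), float(w))

    truth = GroundTruthNetwork(genes=genes, edges=edges, hubs={})
    return truth, list(layers[0])


def cascade_layer_shapes(
    n_layers: int,
    decay: float,
    stimulus_decay: float,
    n_timepoints: int = 8,
) -> np.ndarray:
    """Noise-free unit-weight response of each cascade layer over time.

    Matches the simulator's update order (the stimulus acts on layer 1
    within the same step).  Returns an (n_layers, n_timepoints) array.
    """
    D = np.zeros((n_layers + 1, n_timepoints))
    for t in range(1, n_timepoints):
        D[1, t] = decay * D[1, t - 1] + stimulus_decay ** (t - 1)
        for k in range(2, n_layers + 1):
            D[k, t] = decay * D[k, t - 1] + D[k - 1, t - 1]
    return D[1:]


def design_cascade_amplitudes(
    layer_peaks: tuple[float, ...],
    decay: float,
    stimulus_decay: float,
    n_timepoints: int = 8,
) -> tuple[tuple[float, ...], float]:
    """Layer scales and stimulus strength realising target peak amplitudes.

    Given the desired peak |log2 deviation| of each cascade layer, inverts
    the layer impulse response to the ``layer_scales`` argument of
    :func:`make_cascade_ground_truth` plus the matching stimulus strength,
    so the simulated waves hit the requested peaks (up to weight jitter and
    noise).
    """
    peaks = np.asarray(layer_peaks, dtype=float)
    if (peaks <= 0).any():
        raise ConfigurationError("layer peaks must be positive")
    unit = np.abs(
        cascade_layer_shapes(len(peaks), decay, stimulus_decay, n_timepoints)
    ).max(axis=1)
    strength = peaks[0] / unit[0]
    scales = peaks / (strength * unit)
    return tuple(float(c) for c in scales), float(strength)


def responsive_genes(truth: GroundTruthNetwork, stimulus_targets: list[str]) -> set[str]:
    """Stimulus targets plus all their descendants in the planted network."""
    g = truth.to_networkx()
    out: set[str] = set()
    for t in stimulus_targets:
        if t not in g:
            raise ValueError(f"stimulus target {t!r} not in network")
        out.add(t)
        out |= nx.descendants(g, t)
    return out


def simulate_timecourse(
    truth: GroundTruthNetwork,
    config: SimulationConfig,
    stimulus_targets: list[str] | None = None,
    stimulus_signs: dict[str, int] | None = None,
) -> TimecourseData:
    """Simulate a replicated stimulus-response time course over the planted DAG.

    Each gene's log2 expression is ``baseline + deviation``; deviations start
    at zero and evolve across consecutive timepoints as

        d_child(t+1) = decay * d_child(t)
                       + sum_parents sign * weight * d_parent(t)
                       + N(0, noise_sd^2)

    with a virtual stimulus root whose deviation is ``stimulus_strength *
    stimulus_decay**(t-1)`` at t > 0 (a sustained step when
    ``stimulus_decay`` is 1, a relaxing pulse otherwise) and which feeds the
    ``stimulus_targets`` with unit weight.  Baselines are i.i.d. N(8, 1) per gene, shared across
    replicates; noise is independent per gene, replicate and timepoint.
    """
    rng = np.random.default_rng(config.seed)
    if stimulus_targets is None:
        stimulus_targets = []
    unknown = [t for t in stimulus_targets if t not in set(truth.genes)]
    if unknown:
        raise ValueError(f"unknown stimulus targets: {unknown}")
    signs = dict.fromkeys(stimulus_targets, 1)
    if stimulus_signs:
        signs.update(stimulus_signs)

    genes = truth.genes
    gi = {g: i for i, g in enumerate(genes)}
    n_g, n_r, n_t = len(genes), config.n_replicates, len(config.timepoints)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_g)

    # parent lists per child: (parent index, sign * weight)
    incoming: list[list[tuple[int, float]]] = [[] for _ in range(n_g)]
    for (p, c), (s, w) in truth.edges.items():
        incoming[gi[c]].append((gi[p], s * w))

    cube = np.empty((n_g, n_r, n_t))
    for r in range(n_r):
        dev = np.zeros(n_g)
        cube[:, r, 0] = baseline
        for t in range(1, n_t):
            stim = config.stimulus_strength * config.stimulus_decay ** (t - 1)
            new = config.decay * dev
            for ci in range(n_g):
                for pi, sw in incoming[ci]:
                    new[ci] += sw * dev[pi]
            for target, sgn in signs.items():
                new[gi[target]] += sgn * stim
            if config.noise_sd > 0:
                new += rng.normal(0.0, config.noise_sd, size=n_g)
            dev = new
            cube[:, r, t] = baseline + dev

    replicate_ids = [f"rep{r + 1}" for r in range(n_r)]
    return TimecourseData(
        cube=cube, gene_ids=list(genes), timepoints=config.timepoints,
        replicate_ids=replicate_ids,
    )


def simulate_disruptants(
    truth: GroundTruthNetwork,
    targets: list[str],
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, str], pd.Series]:
    """Simulate a knockdown panel: one array per targeted gene.

    On the targeted array the target's expression is multiplied by
    ``knockdown_factor`` (a shift of ``log2(knockdown_factor)`` on the log2
    scale) and the perturbation propagates to descendants in topological
    order with the signed linear rule ``d_child = sum_parents sign * weight
    * d_parent``; non-descendants stay at baseline up to noise.

    Each array also carries intrinsic biological fluctuations: every gene
    receives an i.i.d. N(0, intrinsic_sd^2) deviation that propagates along
    the network exactly like the knockdown effect.  This makes regulators
    and their targets co-vary across *all* arrays — the statistical signal
    exploited by cross-panel correlation and regression analyses — while
    measurement noise (``noise_sd``) stays unpropagated.  Set both to zero
    for exact deterministic propagation.

    Returns ``(panel, target_map, baseline)`` where ``panel`` is a genes x
    arrays log2 matrix with columns ``kd_<gene>``, ``target_map`` maps array
    id to targeted gene and ``baseline`` is the matched unperturbed
    expression vector.
    """
    rng = np.random.default_rng(config.seed)
    gene_set = set(truth.genes)
    unknown = [t for t in targets if t not in gene_set]
    if unknown:
        raise ValueError(f"unknown knockdown targets: {unknown}")

    genes = truth.genes
    gi = {g: i for i, g in enumerate(genes)}
    n_g = len(genes)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_g)
    topo = truth.topological_order()
    incoming: list[list[tuple[int, float]]] = [[] for _ in range(n_g)]
    for (p, c), (s, w) in truth.edges.items():
        incoming[gi[c]].append((gi[p], s * w))

    shift = np.log2(config.knockdown_factor)
    cols: dict[str, np.ndarray] = {}
    target_map: dict[str, str] = {}
    for target in targets:
        if config.intrinsic_sd > 0:
            eps = rng.normal(0.0, config.intrinsic_sd, size=n_g)
        else:
            eps = np.zeros(n_g)
        dev = np.zeros(n_g)
        for g in topo:
            ci = gi[g]
            total = eps[ci]
            for pi, sw in incoming[ci]:
                total += sw * dev[pi]
            if g == target:
                total += shift
            dev[ci] = total
        values = baseline + dev
        if config.noise_sd > 0:
            values = values + rng.normal(0.0, config.noise_sd, size=n_g)
        array_id = f"kd_{target}"
        if array_id in cols:
            raise ValueError(f"duplicate knockdown target {target!r}")
        cols[array_id] = values
        target_map[array_id] = target

    panel = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    return panel, target_map, pd.Series(baseline, index=panel.index, name="baseline")


def make_flags(
    panel: pd.DataFrame,
    bad_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """All-"Good" quality flags, with an optional fraction of cells set "Bad"."""
    if not (0.0 <= bad_fraction <= 1.0):
        raise ValueError("bad_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    flags = np.full(panel.shape, "Good", dtype=object)
    if bad_fraction > 0:
        mask = rng.random(panel.shape) < bad_fraction
        flags[mask] = "Bad"
    return pd.DataFrame(flags, index=panel.index, columns=panel.columns)
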