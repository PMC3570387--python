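# Methods

`grnhub` reconstructs a directed gene-regulatory network (GRN) from two
complementary expression datasets — a replicated post-stimulus time course
and a single-knockdown ("disruptant") array panel — and ranks candidate
master regulators by their number of direct children in the final
bootstrap-consensus network. This note records the model, the defaults and
why they are what they are, what the synthetic-data generator does and does
not emulate, and the numerical choices that matter.

## Pipeline model

1. **Preprocessing.** Probes flagged "Good" on fewer than 90% of arrays are
   dropped. Each array is loess-normalized in M–A space against a virtual
   reference array (the per-gene median across arrays; span 0.4, degree 1).
   For the knockdown panel, log2 ratios against the virtual median array are
   z-transformed *within each array* (sample standard deviation across
   genes), giving the `DisruptantPanel` whose columns all have mean 0, sd 1.
   A loess smoother is not a projection, so renormalizing a normalized
   matrix moves values by a small fraction (≲5%) of the first-pass
   correction rather than by strictly nothing; the tests assert this
   scale-aware near-idempotency.

2. **Concordant-transcript selection.** For each replicate and timepoint,
   log2 ratios to a reference timepoint (first, then last) are standardized
   *across genes*; a gene is selected when some run of ≥ 2 adjacent
   non-reference timepoints has |z| ≥ 2 with a consistent sign, in every
   replicate (runs need not be aligned across replicates — replicate
   cultures peak at slightly different times). The final list is the union
   over the two references. The criterion is |z| ≥ 2, i.e. *outside* the
   band −2 ≤ z ≤ +2: selecting the inside of the band would retain the
   unchanged transcripts, which cannot be what a "significantly regulated"
   filter means. The replicate rule (`all` / `majority` / `any`), the
   threshold, the window length and the same-sign requirement are all
   configurable.

3. **Time prior (Z1).** With R replicates and T timepoints there are R^T
   "combination" time courses (one replicate chosen per timepoint); for the
   standard 3 × 8 design that is 6561. Each bootstrap draws 25 combinations
   uniformly with replacement (8 × 25 = 200 arrays) and fits a first-order
   stationary dynamic network: for each child, greedy forward–backward
   selection of parents among all genes scoring child(t+1) on parents(t)
   with the shared family scorer (time ordering fixes direction, so no
   acyclicity constraint; self-loops off by default). Over 100 bootstraps
   (default) the bootstrap probability of an edge is its frequency; Z1
   keeps exactly the edges with probability ≥ 0.8. One master seed spawns
   per-bootstrap child seeds, so runs are reproducible and parallelizable.

4. **Array prior (Z2).** In the array targeting gene *i*, every other gene
   *j* with within-array |z| ≥ 2 contributes Z2[i, j] = |z| (the z's sign
   is kept separately for direction prediction). Rows of untargeted genes
   are zero — the prior only informs edges out of knocked-down genes.

5. **Static structure search.** The posterior over DAGs decomposes as
   Σ_child family_score(child, parents) + Σ_edges (−κ + γ1·Z1 + γ2·Z2).
   The family score is a penalized Gaussian additive regression: each
   parent enters through a basis (cubic B-spline with 6 functions by
   default, or linear), ridge penalty λ on basis coefficients, and a BIC
   penalty using the effective degrees of freedom tr(H) of the ridge hat
   matrix (a Laplace/evidence variant is available). Search is greedy
   hill-climbing over single-edge additions, deletions and reversals under
   acyclicity and an in-degree cap (default 3), ties broken
   lexicographically for determinism, best of `n_restarts` random-DAG
   restarts. Consensus: arrays are bootstrap-resampled with replacement
   (default 100×), the search is rerun, and edges with frequency ≥ 0.5
   (configurable; not a published constant) are kept, signed by the
   parent–child Pearson correlation over the full panel.

6. **Hub analysis.** Hubs are ranked by *distinct direct* children
   (min-rank over ties, lexicographic listing; a descendants-based count is
   behind a flag). Validation mirrors the knockdown follow-up: the
   hub–child correlation across the panel predicts the child's direction
   under hub knockdown (positive r → child falls). Gene-set enrichment of
   a hub's children is an upper-tail hypergeometric test with
   Benjamini–Hochberg q-values; gene sets come from user GMT files.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `min_good_fraction` | 0.9 | QC flag retention threshold |
| `loess span` | 0.4 | M–A smoother bandwidth; standard mid-range value |
| `z_threshold`, `min_adjacent` | 2.0, 2 | selection criterion |
| draws, bootstraps | 25, 100 | combinatorial resampling design |
| Z1 threshold | 0.8 | bootstrap-probability cutoff |
| `z_cutoff` (Z2) | 2.0 | knockdown-response threshold |
| κ, γ1, γ2 | 2, 2, 0.5 | edge cost and prior rewards; κ sets sparsity, γ1 makes a Z1-supported edge free, γ2 scales |z|-weighted support |
| `n_basis`, λ | 6, 1.0 | B-spline size and ridge penalty |
| `max_parents` | 3 | in-degree cap; tractability at a few hundred genes |
| consensus threshold | 0.5 | documented as a convention, not a published value |

Sample (n−1) standard deviations are used everywhere a standard deviation
appears; population-style alternatives are configurable where they matter.

## The synthetic generator and the frozen study conditions

The generator plants a signed weighted DAG (`make_ground_truth`: hubs wired
first in a fixed topological order so each hub has exactly its prescribed
children; extra background edges avoid hub parents so the counts stay
exact) and simulates:

* **Time course** — linear-Gaussian lag-1 dynamics on log2 deviations from
  an N(8, 1) baseline: d(t+1) = decay·d(t) + Σ sign·weight·d_parent(t) +
  noise, with a virtual stimulus root ("SFD") whose deviation is
  `strength · stimulus_decay^(t−1)`. A decay < 1 on the stimulus models the
  transient, wave-like programs typical of acute stimuli.
* **Knockdown panel** — one array per target; the target drops by
  log2(knockdown_factor) (default to 20% of baseline) and the shift
  propagates to descendants through the signed linear rule. Every array
  additionally carries *propagated intrinsic variability*: each gene
  receives an N(0, intrinsic_sd²) fluctuation (default 0.8 log2) that
  travels along edges exactly like a perturbation, so regulators and
  targets co-vary across all arrays — the signal that makes cross-panel
  correlation and regression informative, and without which every edge
  would be visible in exactly one array. Measurement noise (`noise_sd`) is
  added last and never propagates. With both set to zero the panel is an
  exact deterministic propagation, which is what the unit tests exercise.

Two frozen scenarios define the study conditions for the acceptance
checks:

* **Selection scenario** — 20 responders among 50 genes, arranged as a
  six-wave cascade (layer sizes 4, 3, 3, 3, 3, 4; each deeper gene has one
  parent in the previous layer), gene decay 0.2, stimulus decay 0.3,
  balanced signs, and per-layer peak amplitudes (7.8, 4.4, 3.2, 3.2, 4.0,
  4.0 log2) realized by inverting the layer impulse response
  (`design_cascade_amplitudes`). The layout is forced by arithmetic: since
  per-slice z-scores satisfy Σz² = G−1, at most ⌊(G−1)/4⌋ ≈ 12 of 50 genes
  can have |z| ≥ 2 at any one timepoint, so 20 responders are only all
  selectable if they peak in staggered waves; narrow waves (fast decay,
  relaxing pulse) and near-homogeneous within-layer amplitudes give every
  layer a window in which it dominates the cross-gene spread. The peak
  amplitudes correspond to strong acute responses (up to ~250-fold for the
  immediate-early layer), which is the regime in which a 2-sd cut with
  40% responders is meaningful at all.
* **Hub scenario** — 50 genes, one hub with 20 children plus 15 background
  edges, hub stimulated in the time course (25 time-prior bootstraps of 25
  draws), 40 knockdowns at factor 0.2 (hub always targeted), measurement
  noise 0.2, 25 static bootstraps at consensus threshold 0.5. The scorer
  uses the linear basis here: at 40 arrays the spline's BIC cost exceeds
  the likelihood gain of a true edge, and the planted dynamics are linear;
  the spline default is for panels with hundreds of arrays.

What the generator does **not** emulate: probe-level chemistry, dye or
spatial artifacts, saturation, batch structure, feedback loops (the truth
is acyclic by construction), nonlinear regulation (propagation is linear),
or replicate structure in the knockdown panel (one array per target).
Passing tests therefore show that the pipeline recovers structure when its
modelling assumptions hold — linear effects, Gaussian noise, sparse graph —
not that it would do so on arbitrary real data.

## Numerical choices and degenerate inputs

* Residual sums of squares are floored at 1e−8·max(yty, 1) so noise-free
  fits cannot produce infinite likelihoods.
* Constant (zero-variance) expression rows standardize to all-zero columns
  and thus carry no score improvement; constant data yields empty parent
  sets rather than errors.
* Families too large for the sample size (basis dimension ≥ n) fall back
  to the linear basis with a warning.
* Hill-climb moves must improve the posterior by > 1e−9; reversal keeps
  acyclicity by checking the residual path before re-adding.
* Zero-variance arrays in `to_zpanel`, missing flags in `filter_flags`,
  cross-gene zero-variance slices in `timecourse_zscores` and infeasible
  hub specifications are hard errors naming the offending array, slice or
  hub.
* Zero-variance rows in correlation computations yield NaN ("no call"),
  not exceptions.

## Known limitations

* The family score is a penalized-regression surrogate for a full Bayesian
  nonparametric-regression marginal likelihood; the scorer interface is
  pluggable so a faithful alternative can be dropped in.
* The graph prior is a per-edge energy (−κ + γ1·Z1 + γ2·Z2); richer prior
  couplings (e.g. between reciprocal edges) are not modelled.
* With one array per knockdown, edges out of untargeted genes are mostly
  informed by propagated intrinsic covariance and the time prior; recall
  on such edges is intrinsically limited, which is why evaluation
  emphasizes precision, hub rank and sign agreement.
* Problem sizes in the shipped scenarios (50 genes, 25-bootstrap
  consensus) were chosen so a full study runs in minutes on one core;
  paper-scale panels (hundreds of genes, 100 bootstraps) use the same code
  paths.
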