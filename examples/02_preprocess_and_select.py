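"""Preprocess a panel and select concordantly regulated transcripts.

Shows the processing chain (flag filter, loess normalization, z-panel) on a
simulated knockdown panel, then runs the cross-gene z-score concordance
selector on a planted stimulus cascade and reports recovery.
"""

from grnhub import ExpressionMatrix, filter_flags, loess_normalize, to_zpanel
from grnhub.pipeline import run_selection_scenario
from grnhub.synthetic import make_flags
from grnhub import SimulationConfig, make_ground_truth, simulate_disruptants

truth = make_ground_truth(200, [("HUB1", 20)], extra_edge_count=40, seed=2)
config = SimulationConfig(n_genes=200, noise_sd=0.2, seed=2)
panel, target_map, _ = simulate_disruptants(truth, truth.genes[:60], config)
flags = make_flags(panel, bad_fraction=0.05, seed=2)

matrix = ExpressionMatrix(values=panel, flags=flags)
filtered = filter_flags(matrix, min_good_fraction=0.9)
print(f"flag filter: {len(matrix.gene_ids)} -> {len(filtered.gene_ids)} genes "
      f"('Good' on >= 90% of arrays)")

normalized = loess_normalize(filtered, span=0.4)
zpanel = to_zpanel(normalized, target_map)
col = zpanel.zvalues.iloc[:, 0]
print(f"z-panel: each array standardized within-array "
      f"(first column mean {col.mean():.2e}, sd {col.std(ddof=1):.3f})")

res = run_selection_scenario(seed=1)
print(f"concordance selection on the stimulus cascade: "
      f"{len(res['selected'])} genes selected, "
      f"recall of 20 planted responders = {res['recall']:.0%}, "
      f"{res['n_false_positives']} false positives")
# a recall of 100% with 0-2 false positives means the |z|>=2,
# two-adjacent-timepoint criterion cleanly separates the planted waves
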