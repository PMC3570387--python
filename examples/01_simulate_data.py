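"""Plant a hub network and simulate both datasets the pipeline consumes.

Builds a 50-gene ground-truth DAG with a 20-child hub, simulates the
replicated stimulus time course and a 40-array knockdown panel, and writes
everything as TSV.
"""

from pathlib import Path

from grnhub import SimulationConfig, make_ground_truth, simulate_disruptants, simulate_timecourse
from grnhub.io import write_matrix, write_target_map, write_truth_edges
from grnhub.synthetic import make_flags

out = Path("scratch/example_data")
out.mkdir(parents=True, exist_ok=True)

truth = make_ground_truth(
    n_genes=50, hub_spec=[("HUB1", 20)], extra_edge_count=15, seed=1
)
print(f"planted network: {len(truth.genes)} genes, {len(truth.edges)} edges, "
      f"hub HUB1 with {truth.children_counts()['HUB1']} children")

config = SimulationConfig(n_genes=50, noise_sd=0.2, seed=1)
tc = simulate_timecourse(truth, config, stimulus_targets=["HUB1"])
print(f"time course cube: {tc.cube.shape} (genes x replicates x timepoints), "
      f"timepoints {tc.timepoints} h")

targets = [g for g in truth.genes][:40]
panel, target_map, baseline = simulate_disruptants(truth, targets, config)
print(f"knockdown panel: {panel.shape[0]} genes x {panel.shape[1]} arrays "
      f"(one per targeted gene, target at <= {config.knockdown_factor:.0%} of baseline)")

write_truth_edges(truth, out / "truth_edges.tsv")
write_matrix(tc.to_frame(), out / "timecourse.tsv")
write_matrix(panel, out / "disruptants.tsv")
write_matrix(make_flags(panel, bad_fraction=0.02, seed=1), out / "flags.tsv")
write_target_map(target_map, out / "targets.tsv")
print(f"wrote TSVs under {out}/")
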