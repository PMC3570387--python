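"""Build the bootstrap dynamic-network time prior from a time course.

Resamples combination time courses (one replicate per timepoint), fits a
first-order dynamic network per bootstrap, and thresholds the resulting
edge confidences into the binary prior Z1.
"""

from grnhub import BootstrapScheme, SimulationConfig, make_ground_truth, simulate_timecourse, time_prior
from grnhub.netsearch import FamilyScorerConfig

truth = make_ground_truth(20, [("HUB1", 8)], extra_edge_count=6, seed=5)
config = SimulationConfig(n_genes=20, noise_sd=0.25, seed=5)
tc = simulate_timecourse(truth, config, stimulus_targets=["HUB1"])

scheme = BootstrapScheme(n_draws_per_bootstrap=25, n_bootstraps=50, seed=5)
print(f"combination space: {scheme.n_combinations(tc)} possible time courses "
      f"({tc.n_replicates} replicates ^ {tc.n_timepoints} timepoints); "
      f"each bootstrap draws {scheme.n_draws_per_bootstrap} of them "
      f"({scheme.n_arrays_per_bootstrap(tc)} arrays)")

conf, z1 = time_prior(
    tc, scheme, scorer_config=FamilyScorerConfig(basis_type="linear"),
    threshold=0.8,
)
n_z1 = int(z1.to_numpy().sum())
print(f"Z1: {n_z1} edges with bootstrap probability >= 0.8")
true_edges = truth.edge_set()
in_truth = sum(1 for i in z1.index for j in z1.columns
               if z1.at[i, j] > 0 and (i, j) in true_edges)
print(f"   of which {in_truth} are planted edges "
      f"({len(true_edges)} planted in total)")
# high-confidence edges concentrate on the planted hub's out-edges because
# the hub responds to the stimulus one step before its children
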