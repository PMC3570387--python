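import numpy as np
import pandas as pd
import pytest

from grnhub.containers import ExpressionMatrix, SimulationConfig
from grnhub.synthetic import make_ground_truth, simulate_disruptants


@pytest.fixture
def star_truth():
    """Five genes, one hub wired to all four others."""
    return make_ground_truth(5, [("H", 4)], extra_edge_count=0, seed=0)


@pytest.fixture
def small_truth():
    """Ten genes, a five-child hub plus a few background edges."""
    return make_ground_truth(10, [("H", 5)], extra_edge_count=3, seed=1)


@pytest.fixture
def noiseless_config():
    return SimulationConfig(n_genes=10, noise_sd=0.0, intrinsic_sd=0.0, seed=0)


@pytest.fixture
def small_panel(small_truth, noiseless_config):
    """Noise-free knockdown panel over the ten-gene network."""
    targets = list(small_truth.genes)
    panel, target_map, baseline = simulate_disruptants(
        small_truth, targets, noiseless_config
    )
    return panel, target_map, baseline


@pytest.fixture
def flagged_matrix():
    """Six genes x ten arrays with a controlled pattern of Good/Bad flags."""
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(8, 1, (6, 10)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"a{j}" for j in range(10)],
    )
    flags = pd.DataFrame("Good", index=values.index, columns=values.columns)
    flags.iloc[1, :1] = "Bad"   # g1: 9/10 Good
    flags.iloc[2, :2] = "Bad"   # g2: 8/10 Good
    flags.iloc[3, :5] = "Bad"   # g3: 5/10 Good
    return ExpressionMatrix(values=values, flags=flags)
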