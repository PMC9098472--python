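import numpy as np
import pandas as pd
import pytest

import spikebench as sb


@pytest.fixture(scope="session")
def small_benchmark():
    """A small default-structure benchmark (120 human + 30 spike proteins)."""
    cfg = sb.SimConfig(n_human=120, n_spike=30, seed=7)
    ds, truth = sb.simulate_benchmark(cfg)
    return cfg, ds, truth


@pytest.fixture()
def tiny_dataset():
    """Handcrafted 3-protein × 4-sample dataset with two missing cells."""
    values = pd.DataFrame(
        {
            "humanOnly_01": [20.0, np.nan, 18.0],
            "humanOnly_02": [21.0, 15.0, 18.5],
            "1:25_01": [20.5, 15.5, np.nan],
            "1:12_01": [20.2, 16.6, 19.0],
        },
        index=["ALBU_HUMAN", "DNAK_ECOLI", "HBA_HUMAN"],
    )
    species = pd.Series(
        ["human", "ecoli", "human"], index=values.index, name="species"
    )
    condition = pd.Series(
        ["humanOnly", "humanOnly", "1:25", "1:12"], index=values.columns, name="condition"
    )
    return sb.IntensityDataset(values=values, species=species, condition=condition)


def two_group_frame(rng, n_genes=50, n1=5, n2=5, shift=0.0, missing=0.0):
    """Random proteins × samples frame with an optional group shift."""
    x = rng.normal(20.0, 1.0, size=(n_genes, n1 + n2))
    x[:, n1:] += shift
    if missing > 0:
        x[rng.random(x.shape) < missing] = np.nan
    cols = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    frame = pd.DataFrame(x, index=[f"g{i}" for i in range(n_genes)], columns=cols)
    groups = np.array(["A"] * n1 + ["B"] * n2)
    return frame, groups
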