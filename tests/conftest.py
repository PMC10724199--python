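import numpy as np
import pandas as pd
import pytest

from stimprofiler import preprocess, synthetic_data as sd
from stimprofiler.matrix import ExpressionMatrix


def small_config(seed: int = 0, **overrides) -> sd.SimulationConfig:
    """A fast-to-simulate configuration used across the unit tests."""
    defaults = dict(
        n_genes=400,
        group_sizes={"HD": 6, "pSS": 5, "SLE": 6},
        n_deg=20,
        n_stim_genes=20,
        ifn_set_size=10,
        n_modules=2,
        module_sizes=(15, 15),
        n_markers=10,
        seed=seed,
    )
    defaults.update(overrides)
    return sd.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    """(counts, lengths, samples, truth) for a small default simulation."""
    return sd.simulate_dataset(small_config(seed=11))


@pytest.fixture(scope="session")
def small_fpkm(small_dataset):
    counts, lengths, _, _ = small_dataset
    return preprocess.fpkm(counts, lengths)


@pytest.fixture()
def tiny_matrix():
    """Hand-sized fpkm matrix for closed-form checks."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 3.0, 4.0],
            "s2": [2.0, 4.0, 6.0, 8.0],
            "s3": [0.0, 1.0, 0.0, 1.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    return ExpressionMatrix(values, "fpkm")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
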