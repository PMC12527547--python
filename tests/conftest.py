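import numpy as np
import pandas as pd
import pytest

from hiermice.data_model import IPDataset, VariableSpec
from hiermice.synthetic import SimConfig, generate_ipd, make_incomplete


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def tiny_spec():
    return [
        VariableSpec("study", "cluster_id", "cluster"),
        VariableSpec("x1", "binary", "covariate"),
        VariableSpec("x2", "count", "covariate"),
        VariableSpec("y", "continuous", "outcome"),
    ]


@pytest.fixture
def tiny_ds(tiny_spec):
    """3 studies x 4 rows with one sporadic and one systematic variable."""
    df = pd.DataFrame(
        {
            "study": ["a"] * 4 + ["b"] * 4 + ["c"] * 4,
            "x1": [0, 1, np.nan, 1, 0, 0, 1, 1] + [np.nan] * 4,
            "x2": [1, 0, 2, 3, 1, np.nan, 0, 2, 4, 1, 0, 2],
            "y": [0.5, 1.2, -0.3, 0.8, 1.1, 0.0, 0.4, -0.2, 0.9, 1.5, 0.1, 0.7],
        }
    )
    return IPDataset(df, tiny_spec)


@pytest.fixture(scope="session")
def binary_scenario():
    """The benchmark scenario used by the heavier recovery checks."""
    return SimConfig(
        outcome_type="binary", n_studies=10, per_study=300,
        heterogeneity="weak", pi_systematic=0.10, sporadic_rate=0.10,
        mechanism="MCAR", seed=101,
    )


@pytest.fixture(scope="session")
def binary_ipd(binary_scenario):
    complete, incomplete, truth = make_incomplete(binary_scenario)
    return complete, incomplete, truth


@pytest.fixture(scope="session")
def continuous_ipd():
    cfg = SimConfig(
        outcome_type="continuous", n_studies=10, per_study=300,
        heterogeneity="moderate", seed=77,
    )
    ds, truth = generate_ipd(cfg)
    return ds, truth
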