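import numpy as np
import pandas as pd
import pytest

from msibatch import FeatureTable, SimulationConfig, generate_batch_experiment


def make_table(values, slides, days, regions, groups=None, orders=None, feat_ids=None):
    """Small hand-built FeatureTable for unit tests."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    feat_ids = feat_ids or [f"f{j}" for j in range(p)]
    obs_meta = pd.DataFrame(
        {
            "obs_id": [f"o{i}" for i in range(n)],
            "slide_id": slides,
            "day": days,
            "measurement_order": orders if orders is not None else range(1, n + 1),
            "region_type": regions,
            "group": groups if groups is not None else [""] * n,
            "row_id": [""] * n,
        }
    )
    feat_meta = pd.DataFrame(
        {
            "feat_id": feat_ids,
            "mz": np.linspace(100, 900, p),
            "role": ["tissue_feature"] * p,
        }
    )
    return FeatureTable(values, obs_meta, feat_meta)


@pytest.fixture(scope="session")
def default_run():
    """One default synthetic batch experiment (the emulated study design)."""
    return generate_batch_experiment(SimulationConfig(), seed=0)


@pytest.fixture(scope="session")
def default_table(default_run):
    return default_run[0]


@pytest.fixture(scope="session")
def default_truth(default_run):
    return default_run[1]
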