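import numpy as np
import pandas as pd
import pytest

from pathdrp.nn import TrainConfig
from pathdrp.pathways import PathwayCollection
from pathdrp.splits import make_folds
from pathdrp.synthetic_data import SyntheticConfig, generate


@pytest.fixture(scope="session")
def default_dataset():
    """The package's default synthetic study conditions."""
    return generate(SyntheticConfig())


@pytest.fixture(scope="session")
def small_dataset():
    """A miniature dataset for fast training tests."""
    cfg = SyntheticConfig(
        n_celllines=40, n_drugs=10, n_genes=60, n_pathways=6,
        pathway_size_range=(4, 12), seed=11,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def small_lco_fold(small_dataset):
    ds, _ = small_dataset
    return make_folds(ds, "LCO", 3).folds[0]


@pytest.fixture
def toy_collection():
    return PathwayCollection(
        "toy",
        (
            ("P1", frozenset({"A", "B"})),
            ("P2", frozenset({"B", "C", "D"})),
            ("P3", frozenset({"E"})),
        ),
        ("A", "B", "C", "D", "E", "F"),
    )


@pytest.fixture
def fast_train_config():
    return TrainConfig(hidden=(16, 8), max_epochs=30, patience=5, seed=0)


@pytest.fixture
def random_prediction_table():
    def make(seed, n_cells=5, n_drugs=8):
        rng = np.random.default_rng(seed)
        rows = [
            (f"c{i}", f"d{j}", rng.normal(), rng.normal())
            for i in range(n_cells)
            for j in range(n_drugs)
        ]
        return pd.DataFrame(rows, columns=["cellline_id", "drug_id", "y_true", "y_pred"])

    return make
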