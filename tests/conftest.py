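import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import sigtransfer as st

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

warnings.filterwarnings("ignore", message=".*zero counts.*")


@pytest.fixture
def tiny_dataset() -> st.ExpressionDataset:
    """8 cells, 4 genes, 2 cell types, 4 samples (2 diseased) — hand-checkable."""
    X = np.array(
        [
            [5, 0, 1, 0],  # Goblet, S1 (healthy)
            [3, 2, 0, 0],  # Goblet, S1
            [0, 4, 0, 1],  # Goblet, S2 (disease)
            [1, 1, 1, 1],  # Goblet, S2
            [2, 0, 3, 0],  # Goblet, S3 (healthy)
            [0, 0, 0, 2],  # Stem,   S3
            [4, 1, 0, 0],  # Stem,   S4 (disease)
            [1, 0, 2, 0],  # Stem,   S4
        ]
    )
    return st.ExpressionDataset.from_arrays(
        dataset_id="TOY",
        X=X,
        gene_ids=["GA", "GB", "GC", "GD"],
        cell_ids=[f"c{i}" for i in range(1, 9)],
        cell_type=["Goblet"] * 5 + ["Stem"] * 3,
        sample_id=["S1", "S1", "S2", "S2", "S3", "S3", "S4", "S4"],
        samples=pd.DataFrame(
            {"disease_state": [0, 1, 0, 1]},
            index=pd.Index(["S1", "S2", "S3", "S4"], name="sample_id"),
        ),
    )


@pytest.fixture(scope="session")
def mini_cohort():
    """A fast 2-dataset cohort with a strong planted 2-gene signature."""
    cfg = st.SimulationConfig(
        n_datasets=2,
        samples_per_dataset=10,
        disease_fraction=0.5,
        cell_types_per_dataset=[["Goblet Cell", "Stem Cell"], ["Goblet Cell"]],
        cells_per_sample_per_type=15.0,
        n_genes=20,
        baseline_log_mean_range=(-0.5, 1.0),
        nb_dispersion=10.0,
        batch_log_sd=0.2,
        signatures=[
            st.SignatureSpec("Goblet Cell", ["G0003", "G0011"], [2.0, 2.0]),
        ],
        seed=7,
    )
    cohort = st.generate_cohort(cfg)
    normalized = [st.normalize_log1p(d) for d in cohort.datasets]
    return cohort, normalized


@pytest.fixture(scope="session")
def mini_slice(mini_cohort) -> st.CellTypeSlice:
    _, normalized = mini_cohort
    return st.slice_cell_type(normalized[0], "Goblet Cell")
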