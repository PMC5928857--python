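import numpy as np
import pandas as pd
import pytest

from timeatlas import SimConfig
from timeatlas.cytof import SAMPLE_COL, CellEventTable
from timeatlas.simulate import generate_cell_events, generate_truth_labels


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale cohort: 12 samples, 300 cells each, 500 genes."""
    return SimConfig(cells_per_sample=300, n_genes=500, seed=11)


@pytest.fixture(scope="session")
def truth_labels(small_config):
    return generate_truth_labels(small_config)


@pytest.fixture(scope="session")
def cell_events(small_config, truth_labels):
    table, _ = generate_cell_events(small_config, truth_labels)
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_events(matrix: np.ndarray, markers, sample="S1", transformed=True):
    """Build a one-sample event table from a raw cells x markers array."""
    data = pd.DataFrame(np.asarray(matrix, dtype=float), columns=list(markers))
    data.insert(0, SAMPLE_COL, sample)
    return CellEventTable(data=data, markers=tuple(markers), transformed=transformed)
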