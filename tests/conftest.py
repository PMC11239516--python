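import numpy as np
import pandas as pd
import pytest

from replifork import GenomeLayout


@pytest.fixture(scope="session")
def layout():
    return GenomeLayout({"chr1": 30_000_000, "chr2": 20_000_000})


@pytest.fixture(scope="session")
def small_layout():
    return GenomeLayout({"chr1": 1_000_000})


@pytest.fixture
def toy_molecules():
    """Hand-written 3-cell molecule table."""
    return pd.DataFrame({
        "cell": ["a", "a", "a", "b", "b", "c"],
        "chrom": ["chr1", "chr1", "chr2", "chr1", "chr1", "chr2"],
        "pos": [10, 60_020, 5_000, 100, 200, 999_999],
        "strand": ["+", "-", "+", "+", "+", "-"],
        "sample": "s1",
        "labeling": "single",
        "delta_t": np.nan,
    })


@pytest.fixture(scope="session")
def dense_cell(layout):
    """One simulated double-pulse cell with clean tracks and no background."""
    from replifork import simulate_whole_cell

    mol, truth = simulate_whole_cell(
        layout, n_forks=40, sampling_rate=0.5, background_rate=0.0,
        scheme="double", seed=101)
    return mol, truth
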