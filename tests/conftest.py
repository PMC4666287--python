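import numpy as np
import pandas as pd
import pytest

from covsel.data_io import CountMatrix, CovariateTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_covariates():
    """Eight units: two-level primary factor, one continuous, one 3-level block."""
    df = pd.DataFrame(
        {
            "line": ["L1"] * 4 + ["L2"] * 4,
            "conc": [0.3, -1.2, 0.5, 1.8, -0.7, 0.2, -0.1, 1.1],
            "block": ["B1", "B2", "B3", "B1", "B2", "B3", "B1", "B2"],
        },
        index=[f"s{i}" for i in range(1, 9)],
    )
    return CovariateTable(
        df,
        {"line": "categorical", "conc": "continuous", "block": "categorical"},
        "line",
        {"line": ["L1", "L2"], "block": ["B1", "B2", "B3"]},
    )


@pytest.fixture
def small_counts(rng, small_covariates):
    counts = rng.poisson(30, size=(25, 8))
    return CountMatrix(
        counts,
        np.array([f"g{i}" for i in range(25)], dtype=object),
        small_covariates.data.index.to_numpy(),
    )
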