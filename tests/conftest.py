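import numpy as np
import pandas as pd
import pytest

from selstrength import ModelSpec, UsedAvailableTable


@pytest.fixture
def figure1_model() -> ModelSpec:
    """Two-habitat model with a categorical (forest/meadow), a continuous
    (elevation, m) covariate and their interaction:
    w = exp(1*forest + 0.01*elevation + 0.01*elevation*forest)."""
    return ModelSpec(
        form="exponential",
        terms=("forest", "elevation", "forest*elevation"),
        beta=[1.0, 0.01, 0.01],
    )


@pytest.fixture
def toy_binomial_table() -> UsedAvailableTable:
    """Six printed rows with one covariate, for brute-force likelihood
    oracles."""
    return UsedAvailableTable(
        pd.DataFrame(
            {
                "used": [1, 1, 1, 0, 0, 0],
                "x": [0.9, 0.4, 0.7, 0.1, 0.3, 0.5],
            }
        )
    )


@pytest.fixture
def toy_weighted_table() -> UsedAvailableTable:
    """Ten printed rows, one covariate, for the weighted-ML grid oracle."""
    return UsedAvailableTable(
        pd.DataFrame(
            {
                "used": [1, 1, 1, 1, 0, 0, 0, 0, 0, 0],
                "x": [0.9, 0.4, 0.7, 0.6, 0.2, 0.5, 1.1, 0.3, 0.7, 0.4],
            }
        )
    )


@pytest.fixture
def toy_strata_table() -> UsedAvailableTable:
    """Three strata of three rows each (one used per stratum), one
    covariate, for the conditional-likelihood grid oracle."""
    return UsedAvailableTable(
        pd.DataFrame(
            {
                "stratum": [0, 0, 0, 1, 1, 1, 2, 2, 2],
                "used": [1, 0, 0, 1, 0, 0, 1, 0, 0],
                "x": [0.9, 0.2, 0.4, 0.2, 0.6, 0.8, 0.3, 0.5, 0.2],
            }
        )
    )
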