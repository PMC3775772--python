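import numpy as np
import pandas as pd
import pytest

from ctrlgenes import ExpressionMatrix, SyntheticConfig, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20130917)


@pytest.fixture
def small_matrix(rng):
    """12 genes x 8 samples of positive random expression values."""
    data = pd.DataFrame(
        rng.lognormal(mean=3.0, sigma=0.7, size=(12, 8)),
        index=[f"g{i:02d}" for i in range(12)],
        columns=[f"s{j}" for j in range(8)],
    )
    return ExpressionMatrix(data, label="toy")


@pytest.fixture(scope="session")
def tiny_study():
    """A small synthetic study shared by cross-module tests."""
    cfg = SyntheticConfig(
        n_genes=400, n_samples=60, n_datasets=4, frac_stable=0.1, seed=7
    )
    return cfg, generate_study(cfg)
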