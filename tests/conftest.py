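import numpy as np
import pandas as pd
import pytest

from naimpute import ExpressionMatrix, FixtureSpec, generate_dataset


def make_matrix(values, scale="log2", features=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    n, s = values.shape
    features = features or [f"f{i}" for i in range(n)]
    samples = samples or [f"s{j}" for j in range(s)]
    return ExpressionMatrix(pd.DataFrame(values, index=features, columns=samples), scale)


@pytest.fixture(scope="session")
def small_dataset():
    """A small complete DIA-like dataset shared across tests (40 proteins, 5v5)."""
    return generate_dataset(FixtureSpec(n_proteins=40, n_samples_per_group=5, seed=7))


@pytest.fixture
def correlated_matrix():
    """60 features x 10 samples with strong pairwise correlation and 20% MCAR."""
    rng = np.random.default_rng(11)
    factor = rng.normal(0, 1, 10)
    X = 20 + 2 * factor[None, :] + rng.normal(0, 0.5, (60, 10))
    mask = rng.random((60, 10)) < 0.2
    # keep every row/column partially observed
    mask[:, 0] = False
    mask[0, :] = False
    Xm = X.copy()
    Xm[mask] = np.nan
    return make_matrix(X), make_matrix(Xm)
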