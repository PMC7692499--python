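import numpy as np
import pandas as pd
import pytest

from gliotype.io_preprocess import ExpressionMatrix
from gliotype.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort with the default structure: 4 subtypes, one diluted."""
    return generate_cohort(
        CohortConfig(n_samples=240, n_genes=1000, n_informative_genes=120, seed=7)
    )


@pytest.fixture()
def random_expr():
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        rng.normal(size=(50, 20)),
        index=[f"G{i}" for i in range(50)],
        columns=[f"S{j}" for j in range(20)],
    )
    return ExpressionMatrix(data)


def two_blob_expr(n_per_blob=150, n_genes=60, sep=8.0, seed=0):
    """Two well-separated sample blobs as a standardized expression matrix."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_genes, n_per_blob))
    b = rng.normal(0.0, 1.0, size=(n_genes, n_per_blob)) + sep
    x = np.hstack([a, b])
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
    data = pd.DataFrame(
        x,
        index=[f"G{i}" for i in range(n_genes)],
        columns=[f"S{j}" for j in range(2 * n_per_blob)],
    )
    membership = np.array([0] * n_per_blob + [1] * n_per_blob)
    return ExpressionMatrix(data, standardized=True), membership
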