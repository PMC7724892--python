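import numpy as np
import pandas as pd
import pytest

from mpn.containers import ExpressionMatrix
from mpn.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """A compact planted cohort shared by read-only tests (n=60, 400 genes)."""
    cfg = SyntheticConfig(n_samples=60, n_genes=400, seed=42)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort (n=100, 3000 genes) shared by read-only tests."""
    cfg = SyntheticConfig(n_samples=100, seed=7)
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_matrix(values, gene_ids=None, sample_ids=None, normalized=False):
    values = np.asarray(values, dtype=float)
    genes = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    samples = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), normalized=normalized
    )
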