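import numpy as np
import pandas as pd
import pytest

from qsarwb.dataset_io import DescriptorTable
from qsarwb.synthetic import SimSpec, gen_descriptor_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def planted():
    """Default planted-signal dataset: y = 6 + 2 x1 - 3 x2 + N(0, 0.1)."""
    table, truth = gen_descriptor_dataset(SimSpec(seed=0))
    return table, truth


@pytest.fixture
def small_table(rng):
    """Well-conditioned 40 x 5 Gaussian table with a linear response."""
    X = rng.standard_normal((40, 5))
    y = 1.0 + X[:, 0] - 2.0 * X[:, 1] + 0.05 * rng.standard_normal(40)
    ids = [f"c{i}" for i in range(40)]
    return DescriptorTable(
        pd.DataFrame(X, index=ids, columns=[f"d{j}" for j in range(5)]),
        pd.Series(y, index=ids),
    )


def make_table(X, y, prefix="d"):
    X = np.asarray(X, dtype=float)
    ids = [f"c{i}" for i in range(len(X))]
    return DescriptorTable(
        pd.DataFrame(X, index=ids, columns=[f"{prefix}{j}" for j in range(X.shape[1])]),
        pd.Series(np.asarray(y, dtype=float), index=ids),
    )
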