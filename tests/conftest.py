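import numpy as np
import pytest

from discosig import MatrixTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_table():
    return MatrixTable(
        row_ids=["MYC", "GFI1", "OTX2"],
        col_ids=["s1", "s2"],
        values=np.array([[1.5, -2.0], [0.0, 3.25], [np.nan, 0.5]]),
        row_meta={"MYC": {"description": "proto-oncogene"}},
    )


def random_table(rng, n_rows=10, n_cols=4, missing_rate=0.0):
    values = rng.normal(size=(n_rows, n_cols)) * 10.0 ** float(rng.integers(-3, 4))
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values[mask] = np.nan
    return MatrixTable(
        row_ids=[f"g{i}" for i in range(n_rows)],
        col_ids=[f"s{j}" for j in range(n_cols)],
        values=values,
    )
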