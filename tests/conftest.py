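import numpy as np
import pandas as pd
import pytest

from bcrisk.schema import COUNT_COL, DEFAULT_FACTORS, LABEL_COL, RiskDataset


def make_dataset(
    n_major: int,
    n_minor: int,
    counts=None,
    seed: int = 0,
    schema=DEFAULT_FACTORS,
) -> RiskDataset:
    """Dataset with random legal codes: n_major label-0 rows then n_minor label-1."""
    rng = np.random.default_rng(seed)
    n = n_major + n_minor
    data = {
        fd.name: rng.choice(np.array(fd.codes), size=n) for fd in schema
    }
    data[COUNT_COL] = np.ones(n, dtype=np.int64) if counts is None else np.asarray(counts)
    data[LABEL_COL] = np.concatenate(
        [np.zeros(n_major, dtype=np.int64), np.ones(n_minor, dtype=np.int64)]
    )
    return RiskDataset(df=pd.DataFrame(data), schema=schema)


@pytest.fixture
def small_ds() -> RiskDataset:
    return make_dataset(n_major=40, n_minor=10, seed=3)


def random_tree_fixture(seed: int, n_rows: int = 8, n_feats: int = 3, n_codes: int = 3):
    """Small random categorical classification fixture for tree oracles."""
    rng = np.random.default_rng(seed)
    X = rng.integers(0, n_codes, size=(n_rows, n_feats)).astype(float)
    y = rng.integers(0, 2, size=n_rows)
    counts = rng.integers(1, 5, size=n_rows).astype(float)
    return X, y, counts
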