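import numpy as np
import pandas as pd
import pytest

from dsanfis import synthetic
from dsanfis.preprocessing import FeatureTable


def random_symmetric_affinity(rng, n):
    """A random valid affinity matrix: symmetric, entries in [0,1], zero diag."""
    A = rng.uniform(0.0, 1.0, (n, n))
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 0.0)
    return A


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def three_blobs():
    """Three tight, well-separated labeled blobs (the exact-recovery regime)."""
    spec = synthetic.BlobSpec(
        centers=[[0.2, 0.2], [0.5, 0.8], [0.8, 0.2]],
        spreads=[0.02, 0.02, 0.02],
        sizes=[25, 25, 25],
        labels=[0, 1, 1],
        seed=42,
    )
    return synthetic.make_blobs(spec)


@pytest.fixture
def small_labelled_table():
    df = pd.DataFrame({
        "a": [0.1, 0.2, 0.8, 0.9, 0.15, 0.85],
        "b": [0.2, 0.1, 0.9, 0.8, 0.25, 0.75],
    })
    return FeatureTable(df, labels=[0, 0, 1, 1, 0, 1])
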