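import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def gaussian_feature_table(centers, n_per_class, sd=1.0, seed=0,
                           prefix="g") -> pd.DataFrame:
    """Labeled feature table of Gaussian blobs (stand-in for EMD features)."""
    rng = np.random.default_rng(seed)
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    dim = centers.shape[1]
    cols = [f"f{i + 1:02d}" for i in range(dim)]
    rows = []
    for ci, mu in enumerate(centers):
        name = f"{prefix}{ci + 1}"
        X = rng.normal(mu, sd, size=(n_per_class, dim))
        for ti in range(n_per_class):
            rows.append({"trial_id": f"{name}_{ti:03d}", "gesture": name,
                         **dict(zip(cols, X[ti]))})
    return pd.DataFrame(rows, columns=["trial_id", "gesture", *cols])


@pytest.fixture
def blob_table():
    return gaussian_feature_table
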