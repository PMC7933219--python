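import numpy as np
import pandas as pd
import pytest

from diffconn.io import CODING, NON_CODING, ExpressionMatrix


def make_matrix(values, feature_ids=None, n_per_cond=None, feature_types=None):
    """Build a small ExpressionMatrix; first half of samples are EC."""
    values = np.asarray(values, dtype=float)
    n_features, n_samples = values.shape
    if n_per_cond is None:
        n_per_cond = n_samples // 2
    if feature_ids is None:
        feature_ids = [f"g{i}" for i in range(n_features)]
    samples = [f"EC_{i}" for i in range(n_per_cond)] + [
        f"TC-EC_{i}" for i in range(n_samples - n_per_cond)
    ]
    cond = pd.Series(
        ["EC"] * n_per_cond + ["TC-EC"] * (n_samples - n_per_cond), index=samples
    )
    if feature_types is None:
        feature_types = [CODING] * n_features
    ft = pd.Series(feature_types, index=feature_ids)
    return ExpressionMatrix(
        pd.DataFrame(values, index=feature_ids, columns=samples), cond, ft
    )


@pytest.fixture
def tiny_em():
    """3 features x 4 samples, 2 conditions."""
    return make_matrix(
        [[2.0, 2.0, 5.0, 5.0], [1.0, 2.0, 1.5, 2.5], [8.0, 7.0, 8.0, 7.0]],
        feature_ids=["fcA", "fcB", "ncC"],
        feature_types=[CODING, CODING, NON_CODING],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
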