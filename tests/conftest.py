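import numpy as np
import pandas as pd
import pytest

from metaeval.dataset import MetDataset


def make_dataset(
    values,
    groups,
    sample_types=None,
    is_flags=None,
    feature_ids=None,
    unit_tag="area",
):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = [f"s{i+1}" for i in range(n)]
    feature_ids = feature_ids or [f"f{j+1}" for j in range(p)]
    return MetDataset(
        values=pd.DataFrame(values, index=sample_ids, columns=feature_ids),
        group=pd.Series(groups, index=sample_ids),
        sample_type=pd.Series(sample_types or ["sample"] * n, index=sample_ids),
        is_internal_standard=None
        if is_flags is None
        else pd.Series(is_flags, index=feature_ids),
        unit_tag=unit_tag,
    )


@pytest.fixture
def tiny():
    """6 samples, 2 balanced groups, 3 features, no missing values."""
    rng = np.random.default_rng(0)
    vals = np.exp(rng.normal(3, 0.5, size=(6, 3)))
    return make_dataset(vals, ["a"] * 3 + ["b"] * 3)


@pytest.fixture
def random_positive():
    """12 samples x 5 features, strictly positive, 2 groups."""
    rng = np.random.default_rng(7)
    vals = np.exp(rng.normal(4, 1.0, size=(12, 5)))
    return make_dataset(vals, ["a"] * 6 + ["b"] * 6)
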