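import numpy as np
import pandas as pd
import pytest

from protarget.io_model import AbundanceMatrix


@pytest.fixture
def tiny_matrix():
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0], [2.0, np.nan, 4.0], [0.5, 1.5, 2.5]],
        index=["A", "B", "C"],
        columns=["s1", "s2", "s3"],
    )
    return AbundanceMatrix(data)


@pytest.fixture
def paired_meta():
    return pd.DataFrame(
        {
            "sample_id": ["s1-T", "s2-T", "s3-T", "s1-N", "s2-N", "s3-N"],
            "subject_id": ["s1", "s2", "s3", "s1", "s2", "s3"],
            "tissue": ["tumor", "tumor", "tumor", "normal", "normal", "normal"],
            "age": [50.0, 60.0, 70.0, 50.0, 60.0, 70.0],
            "gender": ["F", "M", "F", "F", "M", "F"],
            "batch": ["B1"] * 6,
        }
    )


def correlated_vector(rng, base, r):
    """A vector whose sample Pearson correlation with ``base`` is exactly r."""
    b = (base - base.mean()) / base.std()
    e = rng.normal(size=len(base))
    e = e - e.mean()
    e = e - b * (e @ b) / (b @ b)  # orthogonalize
    e = e / e.std()
    return r * b + np.sqrt(1 - r**2) * e
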