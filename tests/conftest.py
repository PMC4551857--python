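import numpy as np
import pandas as pd
import pytest

from neurocoex.expression_io import ExpressionMatrix


@pytest.fixture
def probe_frame():
    """Small probe × sample matrix with two samples."""
    return pd.DataFrame(
        {
            "s1": [2.0, 4.0, 7.0, 1.0],
            "s2": [4.0, 6.0, 7.0, 1.0],
        },
        index=["p1", "p2", "p3", "p4"],
    )


@pytest.fixture
def small_expression():
    """Four genes × four samples with known correlation structure."""
    data = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 4.0, 5.0],
            "s2": [2.0, 4.0, 3.0, 5.0],
            "s3": [3.0, 6.0, 2.0, 5.0],
            "s4": [4.0, 8.0, 1.0, 5.0],
        },
        index=["g1", "g2", "g3", "gflat"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
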