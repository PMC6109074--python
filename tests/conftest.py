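import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from permdeg import CountMatrix, LogExpressionMatrix

# deterministic hypothesis runs
settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def small_counts() -> CountMatrix:
    """Six genes x four samples (2 vs 2), hand-sized for exact checks."""
    df = pd.DataFrame(
        {
            "wt_1": [0, 1, 7, 20, 100, 3],
            "wt_2": [2, 3, 9, 18, 110, 0],
            "ko_1": [1, 0, 30, 5, 95, 4],
            "ko_2": [0, 2, 28, 7, 105, 2],
        },
        index=[f"g{i}" for i in range(6)],
    )
    groups = pd.Series(
        ["wt", "wt", "ko", "ko"], index=["wt_1", "wt_2", "ko_1", "ko_2"]
    )
    return CountMatrix(df, groups)


@pytest.fixture
def gaussian_logmat() -> LogExpressionMatrix:
    """A 200-gene homoscedastic log-expression matrix under the null."""
    rng = np.random.default_rng(42)
    samples = ["a_1", "a_2", "b_1", "b_2"]
    vals = pd.DataFrame(
        rng.normal(loc=5.0, scale=1.0, size=(200, 4)),
        index=[f"g{i:03d}" for i in range(200)],
        columns=samples,
    )
    return LogExpressionMatrix(
        vals, pd.Series(["a", "a", "b", "b"], index=samples)
    )
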