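import numpy as np
import pandas as pd
import pytest


def random_expr(rng: np.random.Generator, n: int, m: int) -> pd.DataFrame:
    return pd.DataFrame(
        rng.normal(7.0, 1.0, size=(n, m)),
        index=[f"g{i}" for i in range(n)],
        columns=[f"s{j}" for j in range(m)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20130)


@pytest.fixture
def small_expr(rng):
    """4 samples x 6 genes of Normal(7,1) values."""
    return random_expr(rng, 6, 4)


@pytest.fixture
def cohort_expr(rng):
    """A 60-gene x 12-sample cohort with one planted +5 outlier."""
    expr = random_expr(rng, 60, 12)
    expr.loc["g7", "s3"] += 5.0
    return expr
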