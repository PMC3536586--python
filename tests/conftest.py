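import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_planted():
    """100 genes x 40 samples, 3 planted metagenes, light noise, no batches."""
    from metanmf import generate_dataset

    return generate_dataset(100, 40, 3, noise_sd=0.1, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_expr(values, prefix_g="g", prefix_s="s") -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"{prefix_g}{i + 1:03d}" for i in range(values.shape[0])],
        columns=[f"{prefix_s}{j + 1:03d}" for j in range(values.shape[1])],
    )
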