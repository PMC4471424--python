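import numpy as np
import pandas as pd
import pytest

from warfdose.cohort import Cohort
from warfdose.schema import DEFAULT_SCHEMA


def make_cohort_frame(n: int, seed: int = 0, with_dose: bool = True) -> pd.DataFrame:
    """Random but schema-valid cohort DataFrame for unit tests."""
    rng = np.random.default_rng(seed)
    cols = {}
    for name in DEFAULT_SCHEMA.covariate_names:
        spec = DEFAULT_SCHEMA[name]
        if spec.kind == "continuous":
            cols[name] = rng.uniform(1.5, 3.0, n).round(3)
        else:
            cols[name] = rng.choice(np.asarray(spec.codes, dtype=float), size=n)
    if with_dose:
        cols["dose_mg_wk"] = rng.uniform(10.0, 60.0, n).round(2)
    return pd.DataFrame(cols)


@pytest.fixture
def small_cohort() -> Cohort:
    return Cohort(make_cohort_frame(12, seed=5))


@pytest.fixture
def blob_toy():
    """Two well-separated 2-D Gaussian blobs, n=40, fixed seed."""
    rng = np.random.default_rng(42)
    n = 40
    X = np.vstack(
        [rng.normal([-2, -2], 0.5, (n // 2, 2)), rng.normal([2, 2], 0.5, (n // 2, 2))]
    )
    z = np.array([0] * (n // 2) + [1] * (n // 2))
    return X, z
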