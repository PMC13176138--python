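import numpy as np
import pandas as pd
import pytest

from brainaging.cohort import CohortTable
from brainaging.synth import SyntheticConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_cohort():
    """Mid-size default-config cohort shared across modules (n=2000)."""
    return generate_cohort(SyntheticConfig(n_subjects=2000, seed=11))


@pytest.fixture(scope="session")
def big_cohort():
    """Larger cohort for recovery-style tests (n=5000)."""
    return generate_cohort(SyntheticConfig(n_subjects=5000, seed=21))


def make_tiny_cohort(n=10, seed=0, psmd=None):
    """Minimal hand-constructed cohort table for I/O and exclusion tests."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "subject_id": [f"T{i:03d}" for i in range(n)],
            "age": rng.uniform(50, 75, n).round(1),
            "sex": np.where(np.arange(n) % 2 == 0, "female", "male"),
            "education": rng.integers(1, 7, n).astype(float),
            "wmh_volume": rng.uniform(0.5, 10, n).round(3),
            "icv": rng.uniform(1300, 1700, n).round(1),
            "psmd": psmd if psmd is not None else rng.normal(2.29e-4, 2e-5, n),
            "morph_a": rng.normal(2.5, 0.2, n),
            "morph_b": rng.normal(3.1, 0.2, n),
        }
    )
    return CohortTable(df, morphometry=["morph_a", "morph_b"])
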