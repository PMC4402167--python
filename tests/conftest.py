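import numpy as np
import pytest

from phenocut.cohort_synth import default_spec, generate_cohort
from phenocut.preprocessing import derive_columns


@pytest.fixture(scope="session")
def small_cohort():
    """A modest derived cohort shared across read-only tests."""
    df = generate_cohort(default_spec(1200), seed=42)
    return derive_columns(df)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
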