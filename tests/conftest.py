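import numpy as np
import pandas as pd
import pytest

from icrpipe.datatypes import ExpressionDataset
from icrpipe.icr_classifier import ICR_PANEL
from icrpipe.synthetic_data import SimConfig, generate_cohort


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same stream regardless of order
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic 30-sample cohort from the default preset."""
    config = SimConfig(n_cohorts=1, n_per_cohort=(30,), seed=77)
    return generate_cohort(config, 0)


@pytest.fixture()
def panel_dataset(rng):
    """A random 20-gene panel dataset with 12 samples."""
    values = pd.DataFrame(
        rng.normal(8.0, 1.0, size=(len(ICR_PANEL), 12)),
        index=list(ICR_PANEL),
        columns=[f"S{i:02d}" for i in range(12)],
    )
    return ExpressionDataset(values, cohort_id="test")
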