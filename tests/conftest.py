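import numpy as np
import pytest

from adcvar.config import CohortConfig
from adcvar.synthetic import generate_cohort

COHORT_SEED = 0  # canonical seed for the calibrated default cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Full default synthetic cohort (114 patients, volumes built)."""
    manifest, scans = generate_cohort(CohortConfig(), seed=COHORT_SEED, volumes=True)
    return manifest, scans


@pytest.fixture(scope="session")
def default_manifest(default_cohort):
    return default_cohort[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
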