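import numpy as np
import pytest

from supergene.synth import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Seeded default cohort: 72 samples, 37:7:28 genotypes, d = 0.8."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def inversion_region():
    cfg = CohortConfig()
    return ("chr1", *cfg.inversion_interval)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
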