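import numpy as np
import pytest

from camp import fit_camp_snp, fixture_d1


@pytest.fixture(scope="session")
def d1():
    """The deterministic small cohort used across the suite."""
    panel, cohort = fixture_d1()
    return panel, cohort


@pytest.fixture(scope="session")
def d1_fit(d1):
    panel, cohort = d1
    return fit_camp_snp(cohort, panel.dosages[:, 0])


@pytest.fixture
def rng():
    return np.random.default_rng(20230804)
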