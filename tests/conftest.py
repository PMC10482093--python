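import numpy as np
import pytest

from nutrigen import SimulationConfig, default_panel, simulate_cohort


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by read-only tests."""
    cfg = SimulationConfig(n_subjects=800, n_snps=24, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
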