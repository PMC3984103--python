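import numpy as np
import pytest

from splitimpute import GeneratorConfig, RunnerRecord, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """1,000 synthetic runners, fixed seed, shared across tests."""
    return generate_cohort(GeneratorConfig(n=1000, seed=42))


@pytest.fixture(scope="session")
def large_cohort():
    """5,000 synthetic runners for statistical checks."""
    return generate_cohort(GeneratorConfig(n=5000, seed=42))


@pytest.fixture
def even_paced_record():
    """A perfectly even-paced finisher: 360 s/km over every section."""
    km = (5, 5, 5, 5, 5, 5, 5, 5, 2.195)
    return RunnerRecord("even", 2013, "M", 40, [360.0 * s for s in km])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
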