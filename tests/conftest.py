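import numpy as np
import pytest

from spatialtme.pipeline import analyze_cohort
from spatialtme.synthetic import GeneratorConfig, simulate_cohort, simulate_sample


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def cohort(default_config):
    """One default synthetic cohort (3 NT + 3 IT), shared across tests."""
    return simulate_cohort(default_config, n_per_group=3, seed=42)


@pytest.fixture(scope="session")
def nt_sample(default_config):
    return simulate_sample(default_config, "NT", seed=7, sample_id="NT_fix")


@pytest.fixture(scope="session")
def analysis(cohort):
    """Full analysis of the shared cohort (expansion graph, 8 CNs)."""
    return analyze_cohort(cohort, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
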