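import numpy as np
import pytest

from neurocoh.synth import CohortConfig, generate_subject


@pytest.fixture(scope="session")
def small_config():
    """A minimal but valid cohort configuration (short recordings)."""
    return CohortConfig(n_per_group=2, record_duration=33.0, seed=11)


@pytest.fixture(scope="session")
def integrated_recording(small_config):
    return generate_subject(small_config, "tme_like", 0)


@pytest.fixture(scope="session")
def segregated_recording(small_config):
    return generate_subject(small_config, "ncse_like", 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
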