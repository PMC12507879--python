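import numpy as np
import pytest

from sarcohab.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_ct_config():
    """A small but non-trivial CT cohort configuration."""
    return GeneratorConfig(modality="CT", n_non_sarcopenia=8, n_sarcopenia=8,
                           roi_shape=(12, 12, 8), seed=42)


@pytest.fixture(scope="session")
def small_ct_cohort(small_ct_config):
    return generate_cohort(small_ct_config)
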