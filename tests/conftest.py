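import numpy as np
import pytest

from pelscore.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: few slides, quarter-size rasters, 256 px patches."""
    return CohortConfig(n_slides=4, slide_size_px=(512, 512), seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
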