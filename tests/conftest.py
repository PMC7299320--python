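import warnings

import numpy as np
import pytest

from texomri.phantom import PhantomConfig, generate_cohort

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_cohort():
    """The default 92-case phantom cohort, generated once per session."""
    return generate_cohort(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast end-to-end checks."""
    cfg = PhantomConfig(
        n_positive=14,
        n_negative=12,
        image_size=(48, 48),
        lesion_radius_range=(7.0, 10.0),
        seed=5,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
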