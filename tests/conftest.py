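import numpy as np
import pytest

from phandose.phantom import PhantomConfig, generate_plan_sample
from phandose.preprocess import PreprocessConfig


@pytest.fixture(scope="session")
def phantom_sample():
    """One deterministic phantom plan on the default desk-scale grid."""
    sample, params = generate_plan_sample(
        PhantomConfig(), "fixture_000", np.random.SeedSequence(42)
    )
    return sample, params


@pytest.fixture(scope="session")
def pp_cfg():
    return PreprocessConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
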