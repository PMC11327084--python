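import numpy as np
import pytest

from bfnet.synthetic_phantoms import PhantomSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small 32px phantom corpus shared by pipeline/trainer/CLI tests."""
    return generate(PhantomSpec(n_images=12, size=32, radius=(2.0, 4.0), seed=7))
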