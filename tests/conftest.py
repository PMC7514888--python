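import numpy as np
import pytest

from lcwd import Image2D, PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def brain_spec():
    return PhantomSpec(height=128, width=128, kind="mixed_brain_like", seed=3)


@pytest.fixture
def brain_phantom(brain_spec):
    return generate_phantom(brain_spec)


@pytest.fixture
def random_image(rng):
    return Image2D(rng.uniform(0, 255, size=(64, 64)))
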