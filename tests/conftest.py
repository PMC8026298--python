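import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_phantom():
    from vesselseg.phantoms import PhantomConfig, generate_phantom
    return generate_phantom(PhantomConfig(image_size=(64, 64), seed=11))
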