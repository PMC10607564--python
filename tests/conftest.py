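import numpy as np
import pytest

from usdespeckle import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_phantoms():
    """Eight deterministic 64x64 clean phantoms."""
    return [
        generate_phantom(PhantomSpec(height=64, width=64, n_lesions=1, seed=s))
        for s in range(8)
    ]


@pytest.fixture(scope="session")
def phantom_128():
    return generate_phantom(PhantomSpec(height=128, width=128, n_lesions=2, seed=7))
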