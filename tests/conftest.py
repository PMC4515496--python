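import numpy as np
import pytest

from hriq import PhantomSpec, generate_phantom
from hriq.phantom import REFERENCE_CLASS_MEANS


@pytest.fixture(scope="session")
def zero_noise_phantom():
    """Piecewise-constant normal-class phantom; every stage is hand-checkable."""
    return generate_phantom(PhantomSpec(noise_cv=0.0, seed=1))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Mild-class phantom with 10% multiplicative speckle."""
    lm, km = REFERENCE_CLASS_MEANS["mild"]
    return generate_phantom(
        PhantomSpec(liver_mean=lm, kidney_mean=km, noise_cv=0.1, seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
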