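import numpy as np
import pytest

from renalmpr.phantom import PhantomSpec, generate_phantom_study


@pytest.fixture(scope="session")
def tiny_study():
    """One misaligned tiny study with the default generator conditions."""
    return generate_phantom_study(PhantomSpec.tiny(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
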