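import numpy as np
import pytest

from dosegan.phantom import PhantomSpec, generate_case


@pytest.fixture(scope="session")
def small_case():
    """One deterministic 32^3 phantom (ct, structures, dose)."""
    spec = PhantomSpec(shape=(32, 32, 32), seed=7)
    return generate_case(spec)


@pytest.fixture(scope="session")
def noiseless_case():
    """Phantom with zero CT/dose noise: analytic dose properties hold exactly."""
    spec = PhantomSpec(shape=(32, 32, 32), seed=7, noise_hu=0.0, noise_dose_frac=0.0)
    return generate_case(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
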