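import numpy as np
import pytest

import filmdose as fd


@pytest.fixture(scope="session")
def models():
    """Rational netT truth models, one per channel."""
    return fd.default_models()


@pytest.fixture(scope="session")
def poly_models():
    """Power-polynomial netOD truth models, one per channel."""
    return fd.default_polynomial_models()


@pytest.fixture(scope="session")
def ref_t():
    """Transmittance of the unexposed synthetic film."""
    return fd.reference_transmittance()


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def square_plan():
    """A 5 Gy, 60 mm square field on a 2 mm grid (fast to reconstruct)."""
    return fd.make_dose_phantom(
        fd.PhantomSpec("uniform_square", 5.0, 60.0, penumbra_sigma_mm=2.0,
                       grid_spacing_mm=2.0, margin_mm=10.0)
    )
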