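import numpy as np
import pytest

from sphtensor.algebra import SphericalTensor
from sphtensor.fields import SphericalTensorField
from sphtensor.derivatives import DerivativeScheme, up_derivative


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_tensor(rng):
    def make(j, imag_type=False):
        return SphericalTensor.random(j, rng, imag_type=imag_type)
    return make


@pytest.fixture
def smooth_field(rng):
    """Factory for random band-limited real-type rank-j fields.

    A Gaussian-filtered white-noise scalar field raised to rank j by
    spectral up-derivatives: genuinely rank-j, smooth, and periodic.
    """
    def make(j, shape=(24, 24, 24), bandwidth=0.5):
        from numpy.fft import fftn, ifftn, fftfreq
        base = rng.standard_normal(shape)
        ks = [2 * np.pi * fftfreq(n) for n in shape]
        KX, KY, KZ = np.meshgrid(*ks, indexing="ij")
        filt = np.exp(-(KX ** 2 + KY ** 2 + KZ ** 2) / (2 * bandwidth ** 2))
        sm = np.real(ifftn(fftn(base) * filt))
        f = SphericalTensorField.from_scalar(sm / np.abs(sm).max())
        sch = DerivativeScheme(mode="fourier")
        for _ in range(j):
            f = up_derivative(f, sch)
        return f
    return make
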