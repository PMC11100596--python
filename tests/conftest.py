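import numpy as np
import pytest
from scipy import ndimage

from protrusion_smt.config import SimConfig


def single_class_config(motion_class: str, **kwargs) -> SimConfig:
    """SimConfig with every molecule in one motion class."""
    mix = {"static": 0.0, "diffusive": 0.0, "processive": 0.0, "stepper": 0.0}
    mix[motion_class] = 1.0
    kwargs.setdefault("motion_mix", mix)
    return SimConfig(**kwargs)


@pytest.fixture
def textured_image():
    """Smooth random image with a noise floor, for registration tests."""
    rng = np.random.default_rng(42)
    base = ndimage.gaussian_filter(rng.random((64, 64)), 2.0)
    return base + 0.05 * rng.standard_normal((64, 64))


@pytest.fixture
def fourier_shift():
    """Subpixel shift by Fourier phase ramp (circular, band-limited)."""

    def _shift(image, dx, dy):
        f = np.fft.fft2(image)
        ky = np.fft.fftfreq(image.shape[0])[:, None]
        kx = np.fft.fftfreq(image.shape[1])[None, :]
        return np.real(np.fft.ifft2(f * np.exp(-2j * np.pi * (ky * dy + kx * dx))))

    return _shift
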