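import numpy as np
import pytest

import zsdeconv as z


@pytest.fixture(scope="session")
def psf_cam():
    """Diffraction-limited Gaussian PSF on the camera grid (62.5 nm px,
    275 nm lateral FWHM)."""
    sigma = 275.0 / (2 * np.sqrt(2 * np.log(2)))
    return z.make_gaussian_psf(sigma, pixel_size=62.5, support=13)


@pytest.fixture(scope="session")
def psf_sr(psf_cam):
    """The same PSF resampled on the 2x super-resolved grid."""
    return z.simulator.upsample_psf(psf_cam, 2)


@pytest.fixture(scope="session")
def camera():
    return z.CameraModel(background_offset_b=100.0, gaussian_variance_beta2=4.0)


@pytest.fixture(scope="session")
def filament_image(psf_cam, camera):
    """Single 15-photon filament image with its clean reference attached."""
    phantom = z.generate_filaments((128, 128), 6, seed=3, pixel_size=62.5)
    return z.render_noisy(phantom, psf_cam, camera, 15.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
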