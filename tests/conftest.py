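import numpy as np
import pytest

from mvsmlm import CameraCalibration, GaussianPSF, PlaneGeometry

PIXEL_SIZE_NM = 108.0
PSF_SIGMA_NM = 130.0
DEFOCUS_DEPTH_NM = 300.0


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def gauss2d():
    return GaussianPSF(PSF_SIGMA_NM, PIXEL_SIZE_NM, None)


@pytest.fixture
def gauss3d():
    return GaussianPSF(PSF_SIGMA_NM, PIXEL_SIZE_NM, DEFOCUS_DEPTH_NM)


@pytest.fixture
def cal_small():
    return CameraCalibration.from_scalars((32, 32), offset=100.0, gain=2.0, readvar=1.6)


@pytest.fixture
def biplane():
    return PlaneGeometry.biplane()


def render_expected(psf, x, y, z, photons, background, shape, window=15):
    """Noiseless expected photo-electron frame with one emitter."""
    frame = np.full(shape, float(background))
    half = window // 2
    ci, cj = int(round(y)), int(round(x))
    patch = photons * psf.evaluate(x - cj + half, y - ci + half, z, window)
    frame[ci - half:ci + half + 1, cj - half:cj + half + 1] += patch
    return frame


def analytic_spline(gauss3d_model, z_min=-900.0, z_max=900.0, z_step=50.0, window=25):
    """Spline PSF sampled from the analytic defocus model (noiseless oracle)."""
    from mvsmlm import fit_spline
    zs = np.arange(z_min, z_max + 0.5 * z_step, z_step)
    c = (window - 1) / 2.0
    stack = np.stack([gauss3d_model.evaluate(c, c, z, window) for z in zs])
    return fit_spline(stack, zs[0], z_step)
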