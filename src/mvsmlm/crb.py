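"""Cramer-Rao bounds on localization precision.

Two calculators are provided:

* :func:`mortensen_crb` — the MLE lateral-precision bound for 2D Gaussian
  fitting with uniform background, evaluated by adaptive numerical quadrature
  of the closed-form integral

      var(x) = (sigma_a^2 / N) / F,
      F = -∫_0^1 t ln t / (t + tau) dt,
      tau = 2 pi sigma_a^2 b / (N a^2),   sigma_a^2 = sigma^2 + a^2 / 12,

  where N is the fitted signal (photo-electrons), b the background per pixel,
  a the pixel size and sigma the PSF width.  In the zero-background limit
  F -> 1 and the bound reduces to sigma_a / sqrt(N).

* :func:`fisher_crb` — the general Fisher-information bound for any
  differentiable (multi)plane PSF model under the sCMOS noise model, with
  per-pixel variance (expected signal + read variance) and parameter vector
  (x, y, z, N, b_1..b_P).  Bounds are the square roots of the diagonal of the
  inverse Fisher matrix.

:func:`emccd_equivalent` maps (N, b) to (N/2, b/2): the excess noise of an
EMCCD gain register is statistically equivalent to halving the signal, and
background photons traverse the same register.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .errors import ConfigurationError, FitError

__all__ = ["CRBInputs2D", "CRBResult", "mortensen_crb", "fisher_crb",
           "emccd_equivalent", "photon_cost_ratio"]


@dataclass(frozen=True)
class CRBInputs2D:
    """Inputs of the 2D Gaussian-fitting bound."""

    photons: float          # N, photo-electrons
    background: float       # b, e- per pixel
    pixel_size_nm: float = 108.0
    sigma_nm: float = 130.0

    def __post_init__(self):
        if self.photons <= 0:
            raise ConfigurationError("photons must be positive")
        if self.background < 0:
            raise ConfigurationError("background must be non-negative")
        if self.pixel_size_nm <= 0 or self.sigma_nm <= 0:
            raise ConfigurationError("pixel size and sigma must be positive")

    @property
    def sigma_a_sq(self) -> float:
        """Pixelation-corrected squared PSF width sigma_a^2 = sigma^2 + a^2/12."""
        return self.sigma_nm**2 + self.pixel_size_nm**2 / 12.0


@dataclass(frozen=True)
class CRBResult:
    """Lower bounds on localization std (nm); sigma_z is NaN when the model
    carries no axial information (pure 2D)."""

    sigma_x: float
    sigma_y: float
    sigma_z: float
    method: str

    def __post_init__(self):
        for name in ("sigma_x", "sigma_y"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise FitError(f"{name} bound is not positive and finite: {v}")


def mortensen_crb(inputs: CRBInputs2D) -> CRBResult:
    """Lateral MLE precision bound by adaptive quadrature (rel. tol 1e-8)."""
    sa2 = inputs.sigma_a_sq
    if inputs.background == 0:
        bound = np.sqrt(sa2 / inputs.photons)
        return CRBResult(bound, bound, np.nan, "mortensen")
    tau = 2.0 * np.pi * sa2 * inputs.background / (inputs.photons * inputs.pixel_size_nm**2)
    val, err = quad(lambda t: -t * np.log(t) / (t + tau), 0.0, 1.0,
                    epsabs=0.0, epsrel=1e-8, limit=200)
    if not np.isfinite(val) or val <= 0 or err > 1e-6 * val:
        raise FitError(f"quadrature did not converge: F={val}, abserr={err}")
    bound = np.sqrt(sa2 / (inputs.photons * val))
    return CRBResult(bound, bound, np.nan, "mortensen")


def _plane_psf(psf, plane):
    return psf[plane] if isinstance(psf, (list, tuple)) else psf


def fisher_information(psf, geom, photons: float, background, z: float,
                       readvar: float = 0.0, window: int = 15):
    """Fisher matrix for theta = (x, y, z, N, b_1..b_P) at an emitter centred
    in a ``window x window`` patch on every plane.  x, y rows are in pixels,
    z in nm."""
    n_planes = geom.n_planes
    bg = np.atleast_1d(np.asarray(background, dtype=float))
    if bg.size == 1:
        bg = np.repeat(bg, n_planes)
    if bg.size != n_planes:
        raise ConfigurationError("background must be scalar or one value per plane")
    npar = 4 + n_planes
    info = np.zeros((npar, npar))
    centre = (window - 1) / 2.0
    for p in range(n_planes):
        model = _plane_psf(psf, p)
        t_p = geom.transmissions[p]
        g = model.gradients(centre, centre, z - geom.focal_offsets[p], window)
        mu = t_p * photons * g["value"] + bg[p]
        derivs = np.zeros((npar,) + mu.shape)
        derivs[0] = t_p * photons * g["dx"]
        derivs[1] = t_p * photons * g["dy"]
        derivs[2] = t_p * photons * g["dz"]
        derivs[3] = t_p * g["value"]
        derivs[4 + p] = 1.0
        w = 1.0 / (mu + readvar)
        flat = derivs.reshape(npar, -1)
        info += (flat * w.ravel()) @ flat.T
    return info


def fisher_crb(psf, geom, photons: float, background, z: float,
               readvar: float = 0.0, pixel_size_nm: float = 108.0,
               window: int = 15) -> CRBResult:
    """CRB for an arbitrary (multi)plane PSF model via the Fisher matrix.

    ``psf`` is a single model shared by all planes or a sequence with one per
    plane; derivatives must be available analytically (both the Gaussian and
    the spline models provide them).  When the model carries no axial
    information the z row is dropped and ``sigma_z`` is NaN.
    """
    info = fisher_information(psf, geom, photons, background, z, readvar, window)
    keep = list(range(info.shape[0]))
    # A purely 2D model has no axial dimension at all: drop z and report NaN.
    # A z-capable model with vanishing axial information (e.g. exactly at the
    # focus of a single plane) is a genuine singularity instead.
    axial_model = any(
        getattr(_plane_psf(psf, p), "defocus_depth_nm", 1.0) is not None
        for p in range(geom.n_planes))
    has_z = axial_model
    if not has_z:
        keep.remove(2)
    elif info[2, 2] <= 1e-300:
        raise FitError("Fisher matrix is singular; no information about z "
                       "(axial derivative vanishes at this position)")
    sub = info[np.ix_(keep, keep)]
    names = [n for i, n in enumerate(["x", "y", "z", "N"]
                                     + [f"b{p}" for p in range(geom.n_planes)])
             if i in keep]
    diag = np.diag(sub)
    if np.any(diag <= 0):
        worst = names[int(np.argmin(diag))]
        raise FitError(f"Fisher matrix is singular; no information about {worst}")
    # scale-invariant degeneracy check on the correlation-normalized matrix
    scale = 1.0 / np.sqrt(diag)
    corr = sub * scale[:, None] * scale[None, :]
    eigval, eigvec = np.linalg.eigh(corr)
    if eigval[0] <= 1e-10:
        worst = names[int(np.argmax(np.abs(eigvec[:, 0])))]
        raise FitError(f"Fisher matrix is singular; null direction dominated by {worst}")
    cov = np.linalg.inv(sub)
    sx = np.sqrt(cov[0, 0]) * pixel_size_nm
    sy = np.sqrt(cov[1, 1]) * pixel_size_nm
    sz = np.sqrt(cov[2, 2]) if has_z else np.nan
    return CRBResult(sx, sy, sz, "fisher")


def emccd_equivalent(photons: float, background: float) -> tuple[float, float]:
    """Map (N, b) to (N/2, b/2): EMCCD excess noise as a 2x signal reduction."""
    if photons < 0 or background < 0:
        raise ConfigurationError("photons and background must be non-negative")
    return photons / 2.0, background / 2.0


def photon_cost_ratio(psf, geom_test, geom_ref, photons: float, background,
                      z_test: float, z_ref: float, readvar: float = 0.0,
                      pixel_size_nm: float = 108.0, window: int = 15,
                      bracket=(0.25, 16.0)) -> float:
    """Photon multiplier m such that ``geom_test`` at m*N matches the lateral
    precision of ``geom_ref`` at N (both evaluated at their own test z)."""
    ref = fisher_crb(psf, geom_ref, photons, background, z_ref, readvar,
                     pixel_size_nm, window).sigma_x

    def gap(m):
        test = fisher_crb(psf, geom_test, m * photons, background, z_test,
                          readvar, pixel_size_nm, window).sigma_x
        return test - ref

    return float(brentq(gap, *bracket, xtol=1e-6))
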