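"""Point-spread-function models.

Two families are provided:

* :class:`GaussianPSF` — an analytic pixel-integrated 2D Gaussian, optionally
  with a defocus curve ``sigma(z) = sigma0 * sqrt(1 + (z/d)^2)`` so the same
  model can describe multiplane stacks.  The defocus depth ``d`` plays the
  role of an effective Rayleigh range of the detection PSF.
* :class:`SplinePSF` — a measured PSF modelled as a 3D cubic B-spline fitted
  to an averaged bead z-stack, the standard approach for multiplane 3D
  fitting.  Evaluation and all spatial derivatives are analytic in the spline
  coefficients.

Both models share one evaluation contract: ``evaluate(x, y, z, window)``
returns a ``window x window`` patch of the *fraction* of the emitter's total
photons expected in each pixel, with ``(x, y)`` the emitter position in the
patch's own 0-based pixel coordinates (x along columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .errors import CalibrationError, ConfigurationError, ZRangeError

__all__ = ["GaussianPSF", "SplinePSF", "evaluate_psf", "average_bead_stack",
           "fit_spline", "calibrate_spline_psfs"]


# ---------------------------------------------------------------------------
# analytic Gaussian
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianPSF:
    """Pixel-integrated Gaussian PSF, optionally defocusing with z.

    Parameters
    ----------
    sigma0_nm : float
        In-focus Gaussian width (nm).
    pixel_size_nm : float
        Back-projected camera pixel size (nm).
    defocus_depth_nm : float or None
        Axial scale ``d`` of the defocus curve; ``None`` means a purely 2D
        model whose width does not change with z.
    """

    sigma0_nm: float = 130.0
    pixel_size_nm: float = 108.0
    defocus_depth_nm: float | None = None

    def __post_init__(self):
        if self.sigma0_nm <= 0 or self.pixel_size_nm <= 0:
            raise ConfigurationError("sigma0 and pixel size must be positive")
        if self.defocus_depth_nm is not None and self.defocus_depth_nm <= 0:
            raise ConfigurationError("defocus depth must be positive")

    # width (nm) and its z derivative
    def sigma_nm(self, z: float) -> float:
        if self.defocus_depth_nm is None:
            return self.sigma0_nm
        return self.sigma0_nm * np.sqrt(1.0 + (z / self.defocus_depth_nm) ** 2)

    def dsigma_dz(self, z: float) -> float:
        if self.defocus_depth_nm is None:
            return 0.0
        d = self.defocus_depth_nm
        return self.sigma0_nm * (z / d**2) / np.sqrt(1.0 + (z / d) ** 2)

    @property
    def z_range(self) -> tuple[float, float]:
        return (-np.inf, np.inf)

    def _edge_terms(self, c: float, s: float, window: int):
        """Pixel-boundary integrals of a 1D unit Gaussian centred at ``c`` (px).

        Returns per-pixel integrals E and their derivatives dE/dc and dE/ds.
        """
        edges = np.arange(window + 1) - 0.5  # pixel i covers [i-0.5, i+0.5)
        u = (edges - c) / (np.sqrt(2.0) * s)
        E = 0.5 * erf(u)
        g = np.exp(-(u**2))
        dE_dc = -g / (np.sqrt(2.0 * np.pi) * s)
        dE_ds = -u * g / (np.sqrt(np.pi) * s)
        return np.diff(E), np.diff(dE_dc), np.diff(dE_ds)

    def evaluate(self, x: float, y: float, z: float, window: int) -> np.ndarray:
        return self.gradients(x, y, z, window)["value"]

    def gradients(self, x: float, y: float, z: float, window: int) -> dict:
        """Patch plus analytic derivatives w.r.t. x, y (px), z (nm), sigma (px)."""
        if window % 2 == 0 or window < 1:
            raise ConfigurationError("window must be odd and positive")
        s_px = self.sigma_nm(z) / self.pixel_size_nm
        Ex, dEx_dx, dEx_ds = self._edge_terms(x, s_px, window)
        Ey, dEy_dy, dEy_ds = self._edge_terms(y, s_px, window)
        P = np.outer(Ey, Ex)
        dPds = np.outer(dEy_ds, Ex) + np.outer(Ey, dEx_ds)  # w.r.t. sigma in px
        return {
            "value": P,
            "dx": np.outer(Ey, dEx_dx),
            "dy": np.outer(dEy_dy, Ex),
            "dz": dPds * (self.dsigma_dz(z) / self.pixel_size_nm),
            "dsigma": dPds,
        }


# ---------------------------------------------------------------------------
# cubic B-spline machinery
# ---------------------------------------------------------------------------

def _bspline_weights(frac: float):
    """Cubic B-spline weights and derivatives for the 4 taps at offset -1..2."""
    t = frac
    w = np.array([
        (1 - t) ** 3 / 6.0,
        (4 - 6 * t**2 + 3 * t**3) / 6.0,
        (1 + 3 * t + 3 * t**2 - 3 * t**3) / 6.0,
        t**3 / 6.0,
    ])
    dw = np.array([
        -((1 - t) ** 2) / 2.0,
        (-12 * t + 9 * t**2) / 6.0,
        (3 + 6 * t - 9 * t**2) / 6.0,
        t**2 / 2.0,
    ])
    return w, dw


def _mirror_index(idx: np.ndarray, n: int) -> np.ndarray:
    """Mirror boundary (reflect about edge samples), matching mode='mirror'."""
    if n == 1:
        return np.zeros_like(idx)
    period = 2 * (n - 1)
    idx = np.abs(idx) % period
    return np.where(idx >= n, period - idx, idx)


@dataclass
class SplinePSF:
    """Measured 3D PSF as a tri-cubic B-spline over an averaged bead stack.

    ``stack`` has shape (nz, ny, nx) with one lateral knot per pixel and axial
    knots every ``z_step`` nm starting at ``z_min``; the emitter sits at the
    stack's lateral centre pixel.  The stack is normalized at build time so
    the in-focus slice sums to 1, giving spline values the same
    fraction-of-photons meaning as the analytic models.
    """

    stack: np.ndarray
    z_min: float
    z_step: float
    normalization: float = 1.0
    _coefficients: np.ndarray | None = None

    #: clamp floor for spline ringing, as a fraction of the PSF peak
    CLAMP_FRACTION = 1e-9

    def __post_init__(self):
        self.stack = np.asarray(self.stack, dtype=float)
        if self.stack.ndim != 3:
            raise CalibrationError("spline PSF stack must be 3D (z, y, x)")
        nz, ny, nx = self.stack.shape
        if ny % 2 == 0 or nx % 2 == 0:
            raise CalibrationError("spline PSF stack must have odd lateral sizes")
        if not np.all(np.isfinite(self.stack)):
            raise CalibrationError("spline PSF stack contains non-finite values")
        if self.z_step <= 0:
            raise CalibrationError("z_step must be positive")
        if self._coefficients is None:
            self._coefficients = ndimage.spline_filter(self.stack, order=3, mode="mirror")
        self._floor = self.CLAMP_FRACTION * self.stack.max()

    @property
    def coefficients(self) -> np.ndarray:
        return self._coefficients

    @property
    def z_range(self) -> tuple[float, float]:
        return (self.z_min, self.z_min + (self.stack.shape[0] - 1) * self.z_step)

    @property
    def center(self) -> tuple[float, float]:
        return ((self.stack.shape[1] - 1) / 2.0, (self.stack.shape[2] - 1) / 2.0)

    def _lateral_block(self, plane: np.ndarray, base: int, w: np.ndarray,
                       window: int, axis: int) -> np.ndarray:
        """Contract one lateral axis with 4 B-spline taps, mirrored at edges."""
        n = plane.shape[axis]
        out = 0.0
        for tap in range(4):
            idx = _mirror_index(np.arange(window) + base + tap - 1, n)
            out = out + w[tap] * np.take(plane, idx, axis=axis)
        return out

    def _patch(self, x: float, y: float, z: float, window: int, wz, dwz=None):
        nz, ny, nx = self.stack.shape
        cy, cx = self.center
        kz = (z - self.z_min) / self.z_step
        zbase = int(np.floor(kz))
        # z contraction -> a (ny, nx) coefficient plane
        zidx = _mirror_index(np.arange(zbase - 1, zbase + 3), nz)
        Cz = np.tensordot(wz, self._coefficients[zidx], axes=(0, 0))
        half = (window - 1) / 2.0
        # sample coordinate for output pixel (i, j): (cy + i - half - (y - half), ...)
        uy0 = cy - y  # coordinate of output row 0 in stack frame
        ux0 = cx - x
        ybase, yfrac = int(np.floor(uy0)), uy0 - np.floor(uy0)
        xbase, xfrac = int(np.floor(ux0)), ux0 - np.floor(ux0)
        wy, dwy = _bspline_weights(yfrac)
        wx, dwx = _bspline_weights(xfrac)
        rows = self._lateral_block(Cz, ybase, wy, window, axis=0)
        value = self._lateral_block(rows, xbase, wx, window, axis=1)
        out = {"value": value}
        if dwz is not None:
            # d/dx: sample coordinate u = cx + j - x, du/dx = -1
            out["dx"] = -self._lateral_block(rows, xbase, dwx, window, axis=1)
            drows = self._lateral_block(Cz, ybase, dwy, window, axis=0)
            out["dy"] = -self._lateral_block(drows, xbase, wx, window, axis=1)
            Czd = np.tensordot(dwz, self._coefficients[zidx], axes=(0, 0))
            rz = self._lateral_block(Czd, ybase, wy, window, axis=0)
            out["dz"] = self._lateral_block(rz, xbase, wx, window, axis=1) / self.z_step
        return out

    def _zweights(self, z: float):
        lo, hi = self.z_range
        if not (lo <= z <= hi):
            raise ZRangeError(f"z={z:.1f} nm outside spline range [{lo:.1f}, {hi:.1f}] nm")
        kz = (z - self.z_min) / self.z_step
        return _bspline_weights(kz - np.floor(kz))

    def evaluate(self, x: float, y: float, z: float, window: int) -> np.ndarray:
        if window % 2 == 0 or window < 1:
            raise ConfigurationError("window must be odd and positive")
        wz, _ = self._zweights(z)
        value = self._patch(x, y, z, window, wz)["value"]
        return np.maximum(value, self._floor)

    def gradients(self, x: float, y: float, z: float, window: int) -> dict:
        if window % 2 == 0 or window < 1:
            raise ConfigurationError("window must be odd and positive")
        wz, dwz = self._zweights(z)
        out = self._patch(x, y, z, window, wz, dwz)
        out["value"] = np.maximum(out["value"], self._floor)
        out["dsigma"] = np.zeros_like(out["value"])  # no width parameter
        return out

    def slice_at(self, z_index: int) -> np.ndarray:
        """The stored (normalized) stack slice at an axial knot."""
        return self.stack[z_index]


def evaluate_psf(psf, x: float, y: float, z: float, window: int) -> np.ndarray:
    """Shared evaluation contract: per-pixel expected photon fractions."""
    return psf.evaluate(x, y, z, window)


# ---------------------------------------------------------------------------
# bead-stack averaging and spline construction
# ---------------------------------------------------------------------------

def _annulus_background(patch: np.ndarray) -> float:
    """Median of the patch's outermost pixel ring — local background estimate."""
    ring = np.concatenate([patch[0], patch[-1], patch[1:-1, 0], patch[1:-1, -1]])
    return float(np.median(ring))


def average_bead_stack(stacks, bead_positions, exclusion_radius: float = 24.0,
                       require_common: bool = True, window: int = 25,
                       transforms=None):
    """Average isolated beads from per-plane z-stacks into one PSF stack per plane.

    Parameters
    ----------
    stacks : sequence of ndarray
        One (nz, rows, cols) z-stack per plane, z-aligned across planes.
    bead_positions : sequence of (x, y)
        Bead positions in the reference camera's pixel frame.
    exclusion_radius : float
        Beads closer than this (px) to any neighbour are discarded.
    require_common : bool
        Discard beads whose window does not fit inside every plane's frame.
    window : int
        Odd patch size used for extraction and averaging.
    transforms : sequence of AffineTransform2D or None
        Per-plane maps *from* the reference frame into each secondary plane's
        pixel frame (identity when None).

    Returns
    -------
    list of ndarray
        One averaged, background-subtracted (nz, window, window) stack per
        plane, with each bead sub-pixel aligned to the window centre.
    """
    from .locfit import fit_gaussian_patch  # deferred: locfit imports this module

    stacks = [np.asarray(s, dtype=float) for s in stacks]
    positions = np.atleast_2d(np.asarray(bead_positions, dtype=float))
    if window % 2 == 0:
        raise ConfigurationError("window must be odd")
    half = window // 2
    n_planes = len(stacks)
    reasons: dict[int, str] = {}

    # neighbour exclusion
    if len(positions) > 1:
        d = np.linalg.norm(positions[:, None] - positions[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        for b in np.where(d.min(axis=1) < exclusion_radius)[0]:
            reasons[b] = f"neighbour within {exclusion_radius} px"

    def plane_xy(b, p):
        if transforms is None or transforms[p] is None:
            return positions[b]
        return transforms[p].apply(positions[b][None])[0]

    # visibility on all planes
    for b in range(len(positions)):
        if b in reasons:
            continue
        for p in range(n_planes):
            x, y = plane_xy(b, p)
            rows, cols = stacks[p].shape[1:]
            visible = half <= round(y) < rows - half and half <= round(x) < cols - half
            if not visible and require_common:
                reasons[b] = f"not visible on plane {p}"
                break

    survivors = [b for b in range(len(positions)) if b not in reasons]
    if not survivors:
        raise CalibrationError(
            "no beads survive selection: "
            + "; ".join(f"bead {b}: {r}" for b, r in reasons.items()))

    averaged = []
    for p in range(n_planes):
        nz = stacks[p].shape[0]
        acc = np.zeros((nz, window, window))
        focus_k = None
        for b in survivors:
            x, y = plane_xy(b, p)
            ci, cj = int(round(y)), int(round(x))
            patch = stacks[p][:, ci - half:ci + half + 1, cj - half:cj + half + 1].copy()
            for k in range(nz):
                patch[k] -= _annulus_background(patch[k])
            # sub-pixel alignment on the sharpest slice
            if focus_k is None:
                focus_k = int(np.argmax(patch.max(axis=(1, 2))))
            fx, fy = fit_gaussian_patch(patch[focus_k])
            shift = (half - fy, half - fx)
            for k in range(nz):
                patch[k] = ndimage.shift(patch[k], shift, order=3, mode="nearest")
            acc += patch
        averaged.append(acc / len(survivors))
    return averaged


def fit_spline(avg_stack: np.ndarray, z_min: float, z_step: float) -> SplinePSF:
    """Fit a tri-cubic interpolating spline to an averaged PSF stack.

    The stack is normalized so its in-focus slice (the slice of maximum peak
    value) sums to 1, and the B-spline coefficients are chosen so the spline
    reproduces every stack sample exactly.

    ``z_min`` must be given in *defocus* coordinates relative to the camera's
    own focal plane: for a stage scan starting at stage position ``z0`` of a
    camera whose focal plane sits at ``offset``, pass ``z_min = z0 - offset``.
    The multiplane fitter always evaluates plane p's spline at
    ``z - focal_offsets[p]``.
    """
    avg_stack = np.asarray(avg_stack, dtype=float)
    if not np.all(np.isfinite(avg_stack)):
        raise CalibrationError("averaged stack contains non-finite values")
    focus = int(np.argmax(avg_stack.max(axis=(1, 2))))
    norm = float(avg_stack[focus].sum())
    if norm <= 0:
        raise CalibrationError("in-focus slice has non-positive total signal")
    return SplinePSF(stack=avg_stack / norm, z_min=float(z_min), z_step=float(z_step),
                     normalization=norm)


def calibrate_spline_psfs(stacks, z_schedule, bead_positions, geom,
                          exclusion_radius: float = 24.0, window: int = 25,
                          transforms=None) -> list[SplinePSF]:
    """Full bead-scan calibration: one spline PSF per camera plane.

    ``stacks`` are corrected (photo-electron) z-scan movies, one per plane,
    whose frames follow ``z_schedule`` (the stage z of every frame); repeated
    frames at the same stage position are averaged first.  Each plane's
    spline is expressed in defocus coordinates relative to that plane's own
    focal offset, so it plugs directly into the multiplane fitter.
    """
    z_schedule = np.asarray(z_schedule, dtype=float)
    zs = np.unique(z_schedule)
    steps = np.diff(zs)
    if len(zs) < 4 or not np.allclose(steps, steps[0]):
        raise CalibrationError("z schedule must be a uniform grid with >= 4 steps")
    per_plane = []
    for s in stacks:
        px = s.pixels if hasattr(s, "pixels") else np.asarray(s, dtype=float)
        per_plane.append(np.stack([px[z_schedule == z].mean(axis=0) for z in zs]))
    if transforms is None:
        transforms = [geom.transform(p) for p in range(geom.n_planes)]
    to_plane = [t.invert() for t in transforms]
    avg = average_bead_stack(per_plane, bead_positions, exclusion_radius,
                             require_common=True, window=window,
                             transforms=to_plane)
    return [fit_spline(avg[p], zs[0] - geom.focal_offsets[p], float(steps[0]))
            for p in range(geom.n_planes)]
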