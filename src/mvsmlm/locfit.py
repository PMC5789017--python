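"""Candidate detection and maximum-likelihood localization fitting.

Detection follows the shot-noise-based significance-map approach: a zero-mean
matched filter is correlated with the photo-electron frame and divided by the
per-pixel noise scale (Poisson variance of the local mean plus the camera's
read-noise variance), giving a map in units of standard deviations.  Local
maxima above a threshold become fit candidates.

Fitting maximizes the sCMOS likelihood in which each corrected pixel value d
with read variance v is treated as (d + v) ~ Poisson(mu + v), so the
log-likelihood is sum (d+v) ln(mu+v) - (mu+v).  Optimization is Fisher-scoring
Newton with Levenberg damping and analytic model gradients; a step is only
accepted if it does not decrease the likelihood, so the objective is
non-decreasing across accepted steps.

Two fit models are provided:

* single plane: theta = (x, y, N, b, sigma), pixel-integrated Gaussian;
* multiplane: joint fit across planes with a (spline or analytic) 3D PSF per
  plane, either with a shared signal split by fixed transmissions
  (theta = (x, y, z, N, b_1..b_P)) or with free per-plane signals
  (theta = (x, y, z, N_1..N_P, b_1..b_P)), the mode used for spectral data
  where the split itself carries the information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (STATUS_CONVERGED, STATUS_FAILED, CameraCalibration,
                   FrameStack, LocalizationTable, UNITS_PHOTOELECTRONS, TABLE_COLUMNS)
from .errors import ConfigurationError, ZRangeError
from .psf import GaussianPSF
from .simulate import PlaneGeometry

__all__ = ["FitConfig", "significance_map", "find_candidates",
           "fit_single_plane", "fit_multiplane", "localize_movie",
           "localize_movie_multiplane"]

FIT_MODE_SHARED = "shared"
FIT_MODE_PER_PLANE = "per_plane"


@dataclass
class FitConfig:
    """Detection and fitting parameters.

    ``threshold`` is in significance units (standard deviations); the default
    of 8 suits biplane data, 6 is typical for quadplane where the per-plane
    signal is smaller.
    """

    threshold: float = 8.0
    window: int = 15
    max_iterations: int = 100
    tolerance: float = 1e-4
    min_separation: float = 3.0
    psf: object = None               # PSF model, or one per plane
    geometry: PlaneGeometry = None
    pixel_size_nm: float = 108.0
    detection_sigma_px: float = 1.2  # matched-filter width
    fit_mode: str = FIT_MODE_SHARED

    def __post_init__(self):
        if self.threshold <= 0:
            raise ConfigurationError("detection threshold must be positive")
        if self.window % 2 == 0 or self.window < 7:
            raise ConfigurationError("fit window must be odd and >= 7")
        if self.fit_mode not in (FIT_MODE_SHARED, FIT_MODE_PER_PLANE):
            raise ConfigurationError(f"unknown fit mode {self.fit_mode!r}")


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _matched_template(sigma_px: float) -> np.ndarray:
    """Zero-mean Gaussian matched filter so constant background cancels."""
    half = max(int(np.ceil(3 * sigma_px)), 2)
    ax = np.arange(-half, half + 1)
    g = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma_px**2))
    g /= g.sum()
    return g - g.mean()


def significance_map(frame: np.ndarray, psf_sigma: float,
                     cal: CameraCalibration) -> np.ndarray:
    """Per-pixel detection significance (sigma units) of a corrected frame."""
    if psf_sigma <= 0:
        raise ConfigurationError("psf_sigma must be positive")
    frame = np.asarray(frame, dtype=float)
    t = _matched_template(psf_sigma)
    response = ndimage.correlate(frame, t, mode="reflect")
    local_mean = ndimage.uniform_filter(frame, size=t.shape[0], mode="reflect")
    variance = np.maximum(local_mean, 0.0) + cal.readvar_map
    noise_sq = ndimage.correlate(variance, t**2, mode="reflect")
    return response / np.sqrt(np.maximum(noise_sq, 1e-300))


def find_candidates(sig_map: np.ndarray, threshold: float,
                    min_separation: float = 3.0) -> list[tuple[int, int]]:
    """Local maxima above ``threshold``; of maxima closer than
    ``min_separation`` px only the most significant survives, ties going to
    the smaller row then column."""
    if threshold <= 0:
        raise ConfigurationError("threshold must be positive")
    sig_map = np.asarray(sig_map, dtype=float)
    is_max = sig_map >= ndimage.maximum_filter(sig_map, size=3, mode="reflect")
    rows, cols = np.nonzero(is_max & (sig_map > threshold))
    if len(rows) == 0:
        return []
    vals = sig_map[rows, cols]
    order = np.lexsort((cols, rows, -vals))  # value desc, then row, then col
    accepted: list[tuple[int, int]] = []
    for k in order:
        r, c = int(rows[k]), int(cols[k])
        if all((r - ar) ** 2 + (c - ac) ** 2 >= min_separation**2
               for ar, ac in accepted):
            accepted.append((r, c))
    return accepted


# ---------------------------------------------------------------------------
# generic damped-Newton MLE on the sCMOS likelihood
# ---------------------------------------------------------------------------

def _loglik(data, readvar, mu_list):
    ll = 0.0
    for d, v, mu in zip(data, readvar, mu_list):
        m = np.maximum(mu + v, 1e-12)
        ll += np.sum((d + v) * np.log(m) - m)
    return ll


def _mle_newton(data, readvar, model, theta0, clamp, scales, tol, max_iter):
    """Fisher-scoring Newton ascent with Levenberg damping.

    ``model(theta)`` returns (mu_list, deriv_list) per plane with deriv_list
    entries of shape (npar, W, W).  Returns (theta, converged, ll_trace).
    """
    theta = clamp(np.asarray(theta0, dtype=float))
    mu, derivs = model(theta)
    ll = _loglik(data, readvar, mu)
    trace = [ll]
    lam = 1e-3
    converged = False
    for _ in range(max_iter):
        npar = len(theta)
        grad = np.zeros(npar)
        hess = np.zeros((npar, npar))
        for d, v, m, D in zip(data, readvar, mu, derivs):
            mv = np.maximum(m + v, 1e-12)
            resid = ((d + v) / mv - 1.0).ravel()
            flat = D.reshape(npar, -1)
            grad += flat @ resid
            hess += (flat / mv.ravel()) @ flat.T
        accepted = False
        for _attempt in range(10):
            damped = hess + lam * np.diag(np.maximum(np.diag(hess), 1e-12))
            try:
                step = np.linalg.solve(damped, grad)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            new_theta = clamp(theta + step)
            try:
                new_mu, new_derivs = model(new_theta)
            except ZRangeError:
                lam *= 10.0
                continue
            new_ll = _loglik(data, readvar, new_mu)
            if new_ll >= ll - 1e-9 * max(abs(ll), 1.0):
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            return theta, False, trace
        delta = np.max(np.abs(new_theta - theta) / scales)
        theta, mu, derivs, ll = new_theta, new_mu, new_derivs, new_ll
        trace.append(ll)
        lam = max(lam / 10.0, 1e-9)
        if delta < tol:
            converged = True
            break
    return theta, converged, trace


# ---------------------------------------------------------------------------
# single-plane Gaussian fit
# ---------------------------------------------------------------------------

def _border_median(patch: np.ndarray) -> float:
    ring = np.concatenate([patch[0], patch[-1], patch[1:-1, 0], patch[1:-1, -1]])
    return float(np.median(ring))


def _centroid_init(patch: np.ndarray) -> tuple[float, float, float, float]:
    """(x, y, N, b) starting values from the background-subtracted patch."""
    b0 = max(_border_median(patch), 1e-3)
    resid = np.clip(patch - b0, 0.0, None)
    total = resid.sum()
    w = patch.shape[0]
    if total <= 0:
        c = (w - 1) / 2.0
        return c, c, 1.0, b0
    ii, jj = np.mgrid[0:w, 0:w]
    return (float((resid * jj).sum() / total), float((resid * ii).sum() / total),
            float(total), b0)


def fit_gaussian_mle(patch: np.ndarray, readvar, sigma0_px: float = 1.2,
                     tolerance: float = 1e-4, max_iterations: int = 100,
                     fixed_sigma: bool = False):
    """MLE of (x, y, N, b, sigma) on one photo-electron patch.

    Returns a dict with the parameter estimates (positions in patch pixel
    coordinates, sigma in px), convergence flag and the log-likelihood trace.
    """
    patch = np.asarray(patch, dtype=float)
    w = patch.shape[0]
    rv = np.broadcast_to(np.asarray(readvar, dtype=float), patch.shape)
    x0, y0, n0, b0 = _centroid_init(patch)
    theta0 = np.array([x0, y0, n0, b0, sigma0_px])

    def clamp(theta):
        t = theta.copy()
        t[0] = np.clip(t[0], -1.0, w)
        t[1] = np.clip(t[1], -1.0, w)
        t[2] = max(t[2], 1e-3)
        t[3] = max(t[3], 1e-6)
        t[4] = np.clip(t[4], 0.3, w) if not fixed_sigma else sigma0_px
        return t

    def model(theta):
        x, y, n, b, s = theta
        g = GaussianPSF(sigma0_nm=s, pixel_size_nm=1.0).gradients(x, y, 0.0, w)
        mu = n * g["value"] + b
        D = np.stack([n * g["dx"], n * g["dy"], g["value"],
                      np.ones_like(mu), n * g["dsigma"]])
        return [mu], [D]

    scales = np.array([1.0, 1.0, max(n0, 1.0), max(b0, 1.0), 1.0])
    theta, converged, trace = _mle_newton([patch], [rv], model, theta0, clamp,
                                          scales, tolerance, max_iterations)
    if theta[2] <= 2e-3:  # signal pinned at the positivity floor
        converged = False
    return {"x": theta[0], "y": theta[1], "photons": theta[2],
            "background": theta[3], "sigma_px": theta[4],
            "converged": converged, "trace": trace}


def fit_gaussian_patch(patch: np.ndarray) -> tuple[float, float]:
    """Sub-pixel (x, y) of a bright isolated spot; used for bead alignment."""
    res = fit_gaussian_mle(patch, readvar=0.0)
    if res["converged"]:
        return res["x"], res["y"]
    x0, y0, _, _ = _centroid_init(patch)
    return x0, y0


def fit_single_plane(frame: np.ndarray, cal: CameraCalibration, candidates,
                     config: FitConfig, frame_index: int = 0) -> LocalizationTable:
    """Fit every candidate on one corrected frame with the Gaussian model.

    Positions are reported in frame pixel coordinates and sigma in nm.
    Non-converged fits are kept with status ``failed``; candidates whose
    windows overlap another candidate are flagged in an ``overlap`` column.
    """
    frame = np.asarray(frame, dtype=float)
    half = config.window // 2
    sigma0_px = config.detection_sigma_px
    if isinstance(config.psf, GaussianPSF):
        sigma0_px = config.psf.sigma0_nm / config.psf.pixel_size_nm
    rows = []
    cand = [(int(r), int(c)) for r, c in candidates]
    for (ci, cj) in cand:
        if not (half <= ci < frame.shape[0] - half and half <= cj < frame.shape[1] - half):
            continue
        patch = frame[ci - half:ci + half + 1, cj - half:cj + half + 1]
        rv = cal.readvar_map[ci - half:ci + half + 1, cj - half:cj + half + 1]
        res = fit_gaussian_mle(patch, rv, sigma0_px=sigma0_px,
                               tolerance=config.tolerance,
                               max_iterations=config.max_iterations)
        overlap = any((ci - oi) ** 2 + (cj - oj) ** 2 < config.window**2
                      for oi, oj in cand if (oi, oj) != (ci, cj))
        rows.append({
            "x": res["x"] + cj - half, "y": res["y"] + ci - half, "z": 0.0,
            "photons": res["photons"], "background": res["background"],
            "sigma": res["sigma_px"] * config.pixel_size_nm,
            "frame": frame_index,
            "status": STATUS_CONVERGED if res["converged"] else STATUS_FAILED,
            "signal0": res["photons"], "overlap": overlap,
        })
    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS) + ["signal0", "overlap"])
    return LocalizationTable(df, config.pixel_size_nm, "single",
                             n_frames=frame_index + 1)


# ---------------------------------------------------------------------------
# multiplane joint fit
# ---------------------------------------------------------------------------

def _plane_psf(psf, p):
    return psf[p] if isinstance(psf, (list, tuple)) else psf


def _valid_z_interval(psfs, geom, margin: float = 0.0) -> tuple[float, float]:
    lo, hi = -np.inf, np.inf
    for p in range(geom.n_planes):
        zr = _plane_psf(psfs, p).z_range
        lo = max(lo, zr[0] + geom.focal_offsets[p])
        hi = min(hi, zr[1] + geom.focal_offsets[p])
    if lo >= hi:
        raise ConfigurationError("plane PSF z ranges do not overlap")
    return lo + margin, hi - margin


def _init_z(patches, psfs, geom, z_lo, z_hi, n_grid: int = 33) -> float:
    """Best-matching z by normalized correlation of patches with PSF slices."""
    w = patches[0].shape[0]
    best_z, best_score = 0.5 * (z_lo + z_hi), -np.inf
    centre = (w - 1) / 2.0
    for z in np.linspace(z_lo, z_hi, n_grid):
        score = 0.0
        for p, patch in enumerate(patches):
            model = _plane_psf(psfs, p).evaluate(centre, centre, z - geom.focal_offsets[p], w)
            pm = patch - patch.mean()
            mm = model - model.mean()
            denom = np.linalg.norm(pm) * np.linalg.norm(mm)
            if denom > 0:
                score += float(np.sum(pm * mm) / denom)
        if score > best_score:
            best_z, best_score = z, score
    return best_z


def fit_multiplane(frames, cals, psfs, geom: PlaneGeometry, candidates,
                   config: FitConfig, transforms=None,
                   frame_index: int = 0) -> LocalizationTable:
    """Joint MLE across planes at the given reference-frame candidates.

    ``frames`` are corrected 2D frames, one per plane; ``candidates`` are
    (row, col) pixels in the reference frame.  ``transforms`` (secondary ->
    reference, one per plane) defaults to the geometry's own.
    """
    n_planes = geom.n_planes
    frames = [np.asarray(f, dtype=float) for f in frames]
    if len(frames) != n_planes or len(cals) != n_planes:
        raise ConfigurationError("one frame and calibration per plane required")
    if transforms is None:
        transforms = [geom.transform(p) for p in range(n_planes)]
    to_plane = [t.invert() for t in transforms]
    half = config.window // 2
    w = config.window
    z_lo, z_hi = _valid_z_interval(psfs, geom)
    z_margin = 0.02 * (z_hi - z_lo)
    per_plane_signals = config.fit_mode == FIT_MODE_PER_PLANE

    rows = []
    for (ri, cj) in candidates:
        # window corners in each plane's own frame
        corners, patches, rvs, ok = [], [], [], True
        for p in range(n_planes):
            xp, yp = to_plane[p].apply([[float(cj), float(ri)]])[0]
            ci_p, cj_p = int(round(yp)), int(round(xp))
            if not (half <= ci_p < frames[p].shape[0] - half
                    and half <= cj_p < frames[p].shape[1] - half):
                ok = False
                break
            corners.append((ci_p - half, cj_p - half))
            patches.append(frames[p][ci_p - half:ci_p + half + 1,
                                     cj_p - half:cj_p + half + 1])
            rvs.append(cals[p].readvar_map[ci_p - half:ci_p + half + 1,
                                           cj_p - half:cj_p + half + 1])
        if not ok:
            continue

        b0 = [max(_border_median(pt), 1e-3) for pt in patches]
        n0 = max(sum(float(np.clip(pt - b, 0, None).sum())
                     for pt, b in zip(patches, b0)), 1.0)
        z0 = _init_z(patches, psfs, geom, z_lo + z_margin, z_hi - z_margin)
        lin = [to_plane[p].linear for p in range(n_planes)]

        if per_plane_signals:
            theta0 = np.concatenate([[float(cj), float(ri), z0],
                                     [n0 * t for t in geom.transmissions], b0])
        else:
            theta0 = np.concatenate([[float(cj), float(ri), z0, n0], b0])
        npar = len(theta0)

        def clamp(theta, _cj=cj, _ri=ri):
            t = theta.copy()
            t[0] = np.clip(t[0], _cj - half, _cj + half)
            t[1] = np.clip(t[1], _ri - half, _ri + half)
            t[2] = np.clip(t[2], z_lo + z_margin, z_hi - z_margin)
            t[3:] = np.maximum(t[3:], 1e-6)
            return t

        def model(theta, _corners=corners, _lin=lin, _npar=npar):
            x, y, z = theta[0], theta[1], theta[2]
            mus, Ds = [], []
            for p in range(n_planes):
                xp, yp = to_plane[p].apply([[x, y]])[0]
                wx, wy = xp - _corners[p][1], yp - _corners[p][0]
                g = _plane_psf(psfs, p).gradients(wx, wy, z - geom.focal_offsets[p], w)
                if per_plane_signals:
                    n_p = theta[3 + p]
                    bg_p = theta[3 + n_planes + p]
                else:
                    n_p = theta[3] * geom.transmissions[p]
                    bg_p = theta[4 + p]
                mu = n_p * g["value"] + bg_p
                D = np.zeros((_npar,) + mu.shape)
                L = _lin[p]
                D[0] = n_p * (L[0, 0] * g["dx"] + L[1, 0] * g["dy"])
                D[1] = n_p * (L[0, 1] * g["dx"] + L[1, 1] * g["dy"])
                D[2] = n_p * g["dz"]
                if per_plane_signals:
                    D[3 + p] = g["value"]
                    D[3 + n_planes + p] = 1.0
                else:
                    D[3] = geom.transmissions[p] * g["value"]
                    D[4 + p] = 1.0
                mus.append(mu)
                Ds.append(D)
            return mus, Ds

        scales = np.ones(npar)
        scales[2] = config.pixel_size_nm  # z step tolerance ~ one pixel in nm
        scales[3:] = np.maximum(theta0[3:], 1.0)
        theta, converged, _ = _mle_newton(patches, rvs, model, theta0, clamp,
                                          scales, config.tolerance,
                                          config.max_iterations)
        # z pinned against the calibrated range -> unreliable
        z_ok = z_lo + 1.5 * z_margin < theta[2] < z_hi - 1.5 * z_margin
        if per_plane_signals:
            signals = theta[3:3 + n_planes]
            total_n = float(signals.sum())
            bgs = theta[3 + n_planes:]
        else:
            total_n = float(theta[3])
            signals = total_n * np.asarray(geom.transmissions)
            bgs = theta[4:]
        row = {
            "x": theta[0], "y": theta[1], "z": theta[2],
            "photons": total_n, "background": float(np.mean(bgs)),
            "sigma": np.nan, "frame": frame_index,
            "status": STATUS_CONVERGED if (converged and z_ok and total_n > 2e-3)
                      else STATUS_FAILED,
        }
        for p in range(n_planes):
            row[f"signal{p}"] = float(signals[p])
        rows.append(row)
    cols = list(TABLE_COLUMNS) + [f"signal{p}" for p in range(n_planes)]
    df = pd.DataFrame(rows, columns=cols)
    return LocalizationTable(df, config.pixel_size_nm, geom.geometry_id,
                             n_frames=frame_index + 1)


# ---------------------------------------------------------------------------
# movie drivers
# ---------------------------------------------------------------------------

def _merge_candidates(cands_ref, values, min_separation):
    order = np.argsort(-np.asarray(values))
    accepted = []
    for k in order:
        r, c = cands_ref[k]
        if all((r - ar) ** 2 + (c - ac) ** 2 >= min_separation**2
               for ar, ac in accepted):
            accepted.append((r, c))
    return accepted


def localize_movie(stack: FrameStack, cal: CameraCalibration,
                   config: FitConfig) -> LocalizationTable:
    """Detect and fit every frame of a corrected single-plane movie."""
    if stack.units != UNITS_PHOTOELECTRONS:
        raise ConfigurationError("movie must be corrected to photo-electrons first")
    tables = []
    for f in range(stack.n_frames):
        frame = stack.pixels[f]
        smap = significance_map(frame, config.detection_sigma_px, cal)
        cands = find_candidates(smap, config.threshold, config.min_separation)
        t = fit_single_plane(frame, cal, cands, config, frame_index=f)
        tables.append(t.df)
    df = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
        columns=list(TABLE_COLUMNS) + ["signal0", "overlap"])
    return LocalizationTable(df, config.pixel_size_nm, "single", stack.n_frames)


def localize_movie_multiplane(stacks, cals, psfs, geom: PlaneGeometry,
                              config: FitConfig,
                              transforms=None) -> LocalizationTable:
    """Detect in every plane, merge candidates in the reference frame, and
    jointly fit each frame of a multiplane acquisition."""
    n_frames = stacks[0].n_frames
    if any(s.n_frames != n_frames for s in stacks):
        raise ConfigurationError("plane movies must be time-synchronized")
    if transforms is None:
        transforms = [geom.transform(p) for p in range(geom.n_planes)]
    tables = []
    for f in range(n_frames):
        cands_ref, values = [], []
        for p in range(geom.n_planes):
            frame = stacks[p].pixels[f]
            smap = significance_map(frame, config.detection_sigma_px, cals[p])
            for (r, c) in find_candidates(smap, config.threshold,
                                          config.min_separation):
                x_ref, y_ref = transforms[p].apply([[float(c), float(r)]])[0]
                cands_ref.append((int(round(y_ref)), int(round(x_ref))))
                values.append(smap[r, c])
        merged = _merge_candidates(cands_ref, values, config.min_separation)
        t = fit_multiplane([s.pixels[f] for s in stacks], cals, psfs, geom,
                           merged, config, transforms, frame_index=f)
        tables.append(t.df)
    cols = list(TABLE_COLUMNS) + [f"signal{p}" for p in range(geom.n_planes)]
    df = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(columns=cols)
    return LocalizationTable(df, config.pixel_size_nm, geom.geometry_id, n_frames)
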