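"""Synthetic-data generator for the full imaging model.

Frames are rendered as: per-pixel ADU = round(Poisson(t_p * N * PSF_p + b)
* gain + offset + Normal(0, sqrt(readvar) * gain)), i.e. Poisson photon
statistics on signal plus background, per-pixel camera gain/offset, and
Gaussian read noise applied in ADU after the gain.  Splitting across planes
uses fixed per-plane transmission fractions (50/50 biplane, 1/4-per-camera
quadplane, dichroic fractions for spectral runs) and per-plane focal offsets.

Emitter blinking is supplied by the caller as explicit on-frame sets; no
photoswitching kinetics are modelled.  Spectral channel signals are generated
by multinomial thinning of a single Poisson photon budget, the physically
consistent model of one emission stream split through sequential dichroics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import UNITS_ADU, CameraCalibration, FrameStack
from .errors import ConfigurationError
from .register import AffineTransform2D

__all__ = [
    "PlaneGeometry", "EmitterGroundTruth", "DyeSignature",
    "simulate_movie", "simulate_bead_zstack", "simulate_spectral_localizations",
]

#: Default plane spacings (nm) of the three supported multi-camera layouts.
BIPLANE_SPACING_NM = 600.0
QUADPLANE_SPACING_NM = 500.0
SPECTRAL_SPACING_NM = 100.0


@dataclass(frozen=True)
class PlaneGeometry:
    """Focal offsets, transmission fractions and registration of each camera."""

    focal_offsets: tuple
    transmissions: tuple
    inter_camera_transforms: tuple = None  # secondary -> reference; None = identity
    geometry_id: str = "custom"

    def __post_init__(self):
        off = tuple(float(v) for v in self.focal_offsets)
        tr = tuple(float(v) for v in self.transmissions)
        if len(off) != len(tr):
            raise ConfigurationError("offsets and transmissions must have equal length")
        if len(off) not in (1, 2, 4):
            raise ConfigurationError("supported plane counts are 1, 2 and 4")
        if abs(sum(tr) - 1.0) > 1e-9:
            raise ConfigurationError(f"transmissions must sum to 1, got {sum(tr)}")
        if any(b <= a for a, b in zip(off, off[1:])):
            raise ConfigurationError("focal offsets must be strictly increasing")
        transforms = self.inter_camera_transforms
        if transforms is None:
            transforms = tuple([None] * len(off))
        elif len(transforms) != len(off):
            raise ConfigurationError("one transform per plane required (None for identity)")
        object.__setattr__(self, "focal_offsets", off)
        object.__setattr__(self, "transmissions", tr)
        object.__setattr__(self, "inter_camera_transforms", tuple(transforms))

    @property
    def n_planes(self) -> int:
        return len(self.focal_offsets)

    def transform(self, plane: int) -> AffineTransform2D:
        t = self.inter_camera_transforms[plane]
        return AffineTransform2D.identity() if t is None else t

    # -- standard layouts ---------------------------------------------------
    @classmethod
    def single_plane(cls) -> "PlaneGeometry":
        return cls((0.0,), (1.0,), geometry_id="single")

    @classmethod
    def biplane(cls, spacing_nm: float = BIPLANE_SPACING_NM) -> "PlaneGeometry":
        h = spacing_nm / 2.0
        return cls((-h, h), (0.5, 0.5), geometry_id="biplane")

    @classmethod
    def quadplane(cls, spacing_nm: float = QUADPLANE_SPACING_NM) -> "PlaneGeometry":
        s = spacing_nm
        return cls((-1.5 * s, -0.5 * s, 0.5 * s, 1.5 * s), (0.25,) * 4,
                   geometry_id="quadplane")

    @classmethod
    def spectral(cls, spacing_nm: float = SPECTRAL_SPACING_NM,
                 transmissions=(0.25, 0.25, 0.25, 0.25)) -> "PlaneGeometry":
        s = spacing_nm
        return cls((-1.5 * s, -0.5 * s, 0.5 * s, 1.5 * s), tuple(transmissions),
                   geometry_id="spectral")


@dataclass(frozen=True)
class EmitterGroundTruth:
    """True position, brightness and on-frames of one simulated emitter."""

    x: float
    y: float
    z: float = 0.0
    photons: float = 5000.0
    on_frames: frozenset | None = None  # None = on in every frame
    dye_id: int = 0

    def __post_init__(self):
        if self.photons <= 0:
            raise ConfigurationError("emitter photon count must be positive")
        if self.on_frames is not None:
            object.__setattr__(self, "on_frames", frozenset(int(f) for f in self.on_frames))

    def is_on(self, frame: int) -> bool:
        return self.on_frames is None or frame in self.on_frames


@dataclass(frozen=True)
class DyeSignature:
    """Expected fraction of a dye's emission landing in each color channel."""

    channel_fractions: tuple

    def __post_init__(self):
        fr = tuple(float(v) for v in self.channel_fractions)
        if any(v < 0 for v in fr):
            raise ConfigurationError("channel fractions must be non-negative")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ConfigurationError("channel fractions must sum to 1")
        object.__setattr__(self, "channel_fractions", fr)


def _per_plane(value, n_planes, name):
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, n_planes)
    if arr.size != n_planes:
        raise ConfigurationError(f"{name} must be scalar or one value per plane")
    return arr


def _psf_for_plane(psf, plane):
    return psf[plane] if isinstance(psf, (list, tuple)) else psf


def _render_emitter(frame, psf, x, y, z, photons, window):
    """Add an emitter's expected photon counts into ``frame`` (in place)."""
    rows, cols = frame.shape
    half = window // 2
    ci, cj = int(round(y)), int(round(x))
    if not (0 <= ci < rows and 0 <= cj < cols):
        warnings.warn(f"emitter at ({x:.1f}, {y:.1f}) outside frame; clipped")
    patch = photons * psf.evaluate(x - cj + half, y - ci + half, z, window)
    r0, r1 = max(ci - half, 0), min(ci + half + 1, rows)
    c0, c1 = max(cj - half, 0), min(cj + half + 1, cols)
    if r0 >= r1 or c0 >= c1:
        return
    frame[r0:r1, c0:c1] += patch[r0 - ci + half:r1 - ci + half,
                                 c0 - cj + half:c1 - cj + half]


def _digitize(expected, cal, rng):
    """Poisson photon noise, gain/offset, Gaussian read noise -> integer ADU."""
    photons = rng.poisson(np.maximum(expected, 0.0))
    adu = (photons * cal.gain_map + cal.offset_map
           + rng.normal(0.0, 1.0, expected.shape) * np.sqrt(cal.readvar_map) * cal.gain_map)
    return np.maximum(np.round(adu), 0.0).astype(np.uint16)


def simulate_movie(emitters, psf, geom: PlaneGeometry, cal, background,
                   n_frames: int, seed: int, window: int = 15) -> list[FrameStack]:
    """Render one raw ADU movie per plane.

    ``cal`` may be a single :class:`CameraCalibration` shared by all planes or
    a sequence with one per plane; ``background`` (e-/pixel/plane) likewise
    scalar or per-plane.  ``seed`` is mandatory: identical inputs and seed
    give bit-identical stacks.
    """
    if seed is None:
        raise ConfigurationError("seed is mandatory")
    rng = np.random.default_rng(seed)
    cals = list(cal) if isinstance(cal, (list, tuple)) else [cal] * geom.n_planes
    if len(cals) != geom.n_planes:
        raise ConfigurationError("one calibration per plane required")
    bg = _per_plane(background, geom.n_planes, "background")

    # pre-compute emitter positions in each plane's own pixel frame
    plane_xy = []
    for p in range(geom.n_planes):
        to_plane = geom.transform(p).invert()
        plane_xy.append([to_plane.apply([[e.x, e.y]])[0] for e in emitters])

    stacks = []
    for p in range(geom.n_planes):
        c = cals[p]
        t_p, off_p = geom.transmissions[p], geom.focal_offsets[p]
        psf_p = _psf_for_plane(psf, p)
        frames = np.empty((n_frames,) + c.shape, dtype=np.uint16)
        for f in range(n_frames):
            expected = np.full(c.shape, bg[p], dtype=float)
            for e, (xp, yp) in zip(emitters, plane_xy[p]):
                if e.is_on(f):
                    _render_emitter(expected, psf_p, xp, yp, e.z - off_p,
                                    t_p * e.photons, window)
            frames[f] = _digitize(expected, c, rng)
        stacks.append(FrameStack(pixels=frames, units=UNITS_ADU, camera_id=f"cam{p}"))
    return stacks


def simulate_bead_zstack(bead_positions, psf, geom: PlaneGeometry, cal,
                         z_range, z_step: float, frames_per_z: int, seed: int,
                         photons: float = 20000.0, background: float = 10.0,
                         window: int = 25):
    """Simulate a piezo z-scan of coverslip beads through all focal planes.

    Returns (stacks, z_schedule): one raw stack per plane ordered by
    increasing stage z, plus the stage z of every frame.  Bead brightness is
    constant across z (no bleaching).
    """
    z_lo, z_hi = float(z_range[0]), float(z_range[1])
    if z_step <= 0:
        raise ConfigurationError("z_step must be positive")
    if z_lo > min(geom.focal_offsets) or z_hi < max(geom.focal_offsets):
        raise ConfigurationError("z_range must cover all focal-plane offsets")
    z_values = np.arange(z_lo, z_hi + 0.5 * z_step, z_step)
    schedule = np.repeat(z_values, frames_per_z)
    emitters_at = lambda z: [EmitterGroundTruth(x=x, y=y, z=z, photons=photons)
                             for x, y in np.atleast_2d(bead_positions)]
    # render one sub-movie per stage z, all planes, then concatenate
    per_plane = [[] for _ in range(geom.n_planes)]
    rng = np.random.default_rng(seed)
    for z in z_values:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        stacks = simulate_movie(emitters_at(z), psf, geom, cal, background,
                                frames_per_z, seed=sub_seed, window=window)
        for p, s in enumerate(stacks):
            per_plane[p].append(s.pixels)
    stacks = [FrameStack(np.concatenate(chunks), units=UNITS_ADU, camera_id=f"cam{p}")
              for p, chunks in enumerate(per_plane)]
    return stacks, schedule


def simulate_spectral_localizations(dyes, n_per_dye: int, mean_photons: float,
                                    seed: int, readnoise_sigma: float = 0.0):
    """Draw per-localization channel signal 4-vectors for a set of dyes.

    Each localization receives a Poisson total photon budget which is
    multinomially split across the 4 channels by the dye's signature;
    optional Gaussian noise emulates per-channel fit error.

    Returns (signals, labels): (n, 4) channel signals (e-) and true dye ids.
    """
    if seed is None:
        raise ConfigurationError("seed is mandatory")
    rng = np.random.default_rng(seed)
    signals, labels = [], []
    for d, dye in enumerate(dyes):
        frac = np.asarray(dye.channel_fractions)
        totals = rng.poisson(mean_photons, size=n_per_dye)
        for total in totals:
            s = rng.multinomial(total, frac).astype(float)
            if readnoise_sigma > 0:
                s += rng.normal(0.0, readnoise_sigma, size=len(frac))
            signals.append(s)
            labels.append(d)
    return np.asarray(signals, dtype=float), np.asarray(labels, dtype=int)
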