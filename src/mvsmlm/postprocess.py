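"""Bead tracking, precision statistics, drift correction, z rescale, rendering.

Bead precision is measured by tracking every frame-0 localization through the
movie (2 px capture radius), discarding tracks missing from more than 10% of
frames, and taking the standard deviation of the tracked positions.  Drift is
estimated by cross-correlating super-resolution histograms of temporal
segments against the first segment, with sub-bin quadratic peak
interpolation, and linearly interpolating the per-segment offsets to frames.
Axial positions from multiplane fitting are multiplied by 0.79 as a
first-order correction for the spherical aberration of imaging into an
aqueous sample with an oil objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .core import LocalizationTable
from .errors import ConfigurationError

__all__ = ["Track", "DriftTrace", "track_beads", "filter_tracks",
           "precision_stats", "drift_correct", "rescale_z", "render",
           "Z_RESCALE_FACTOR"]

#: First-order spherical-aberration correction applied to fitted z values.
Z_RESCALE_FACTOR = 0.79


@dataclass
class Track:
    """One bead followed through a movie; ``rows`` maps frame -> table row."""

    bead_id: int
    seed_xy: tuple
    rows: dict            # frame index -> row index into the table
    ambiguous_frames: set = field(default_factory=set)

    def missing_frames(self, movie_length: int) -> int:
        return movie_length - len(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class DriftTrace:
    """Per-segment (dx, dy[, dz]) offsets in nm; the first segment anchors 0."""

    offsets: np.ndarray    # (n_segments, 2 or 3)
    segment_frames: int

    def __post_init__(self):
        self.offsets = np.atleast_2d(np.asarray(self.offsets, dtype=float))
        if np.any(self.offsets[0] != 0):
            raise ConfigurationError("first drift segment must be the zero anchor")


def track_beads(table: LocalizationTable, radius: float = 2.0) -> list[Track]:
    """Assign localizations to frame-0 seed positions within ``radius`` px.

    Each later localization joins the track whose seed is nearest within the
    radius; when two localizations in one frame match the same seed the nearer
    one wins and the frame is flagged ambiguous.  Seeds are never updated.
    """
    df = table.df
    if len(df) == 0:
        return []
    frame0 = df[df["frame"] == 0]
    seeds = frame0[["x", "y"]].to_numpy()
    tracks = [Track(bead_id=b, seed_xy=(s[0], s[1]), rows={0: int(i)})
              for b, (i, s) in enumerate(zip(frame0.index, seeds))]
    if not tracks:
        return []
    xy = df[["x", "y"]].to_numpy()
    frames = df["frame"].to_numpy()
    best = {}  # (bead, frame) -> (dist, row)
    for row in range(len(df)):
        f = int(frames[row])
        if f == 0:
            continue
        d = np.linalg.norm(seeds - xy[row], axis=1)
        b = int(np.argmin(d))
        if d[b] > radius:
            continue  # unassigned
        key = (b, f)
        if key in best:
            tracks[b].ambiguous_frames.add(f)
            if d[b] >= best[key][0]:
                continue
        best[key] = (d[b], row)
    for (b, f), (_, row) in best.items():
        tracks[b].rows[f] = row
    return tracks


def filter_tracks(tracks: list[Track], movie_length: int,
                  max_missing: float = 0.10, paired_tracks=None) -> list[Track]:
    """Keep tracks missing from at most ``max_missing`` of the frames.

    The rule is strict: a track missing *more than* 10% of frames is
    discarded, so 10/100 missing passes and 11/100 fails.  With
    ``paired_tracks`` (same beads on a second camera, matched by bead id) a
    track must pass on both cameras.
    """
    if movie_length <= 0:
        raise ConfigurationError("movie_length must be positive")
    budget = max_missing * movie_length

    def passes(t: Track) -> bool:
        return t.missing_frames(movie_length) <= budget

    if paired_tracks is None:
        return [t for t in tracks if passes(t)]
    partner = {t.bead_id: t for t in paired_tracks}
    return [t for t in tracks
            if passes(t) and t.bead_id in partner and passes(partner[t.bead_id])]


def precision_stats(track: Track, table: LocalizationTable) -> dict:
    """Sample std of tracked positions (nm, unbiased n-1 estimator) and mean
    fitted signal/background over the frames where the bead was found."""
    if len(track) < 10:
        return {"sufficient": False, "n": len(track)}
    rows = sorted(track.rows.values())
    sub = table.df.loc[rows]
    a = table.pixel_size_nm
    return {
        "sufficient": True,
        "n": len(track),
        "std_x": float(sub["x"].std(ddof=1) * a),
        "std_y": float(sub["y"].std(ddof=1) * a),
        "std_z": float(sub["z"].std(ddof=1)),
        "mean_photons": float(sub["photons"].mean()),
        "mean_background": float(sub["background"].mean()),
    }


def _quadratic_peak(profile: np.ndarray, k: int) -> float:
    """Sub-bin peak position by a parabola through the peak and neighbours."""
    if k <= 0 or k >= len(profile) - 1:
        return float(k)
    y0, y1, y2 = profile[k - 1], profile[k], profile[k + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return float(k)
    return float(k + 0.5 * (y0 - y2) / denom)


def _xcorr_offset(ref: np.ndarray, img: np.ndarray) -> np.ndarray:
    """(dy, dx) shift of ``img`` relative to ``ref`` in bins, by
    cross-correlation with quadratic sub-bin interpolation."""
    corr = fftconvolve(img, ref[::-1, ::-1], mode="full")
    k = np.unravel_index(np.argmax(corr), corr.shape)
    py = _quadratic_peak(corr[:, k[1]], k[0])
    px = _quadratic_peak(corr[k[0], :], k[1])
    centre = np.array(ref.shape) - 1.0
    return np.array([py, px]) - centre


def drift_correct(table: LocalizationTable, segment_frames: int = 1000,
                  bin_size_nm: float = 20.0, axial: bool = False,
                  min_locs: int = 100):
    """Estimate and subtract lateral (optionally axial) drift.

    The movie is split into consecutive ``segment_frames`` blocks; each block
    is rendered into a 2D histogram at ``bin_size_nm`` and cross-correlated
    against the first block.  Per-frame offsets are linearly interpolated
    between segment centres and subtracted.  Segments with fewer than
    ``min_locs`` localizations get offsets interpolated from their
    neighbours (with a warning).

    Returns (corrected_table, DriftTrace).
    """
    if table.n_frames < 2 * segment_frames:
        raise ConfigurationError("movie must span at least 2 drift segments")
    df = table.df.copy()
    a = table.pixel_size_nm
    x_nm = df["x"].to_numpy() * a
    y_nm = df["y"].to_numpy() * a
    frames = df["frame"].to_numpy()
    n_seg = int(np.ceil(table.n_frames / segment_frames))
    seg_of = np.minimum(frames // segment_frames, n_seg - 1)

    # common histogram support across segments
    pad = 2 * bin_size_nm
    xe = np.arange(x_nm.min() - pad, x_nm.max() + pad + bin_size_nm, bin_size_nm)
    ye = np.arange(y_nm.min() - pad, y_nm.max() + pad + bin_size_nm, bin_size_nm)

    def hist(mask):
        h, _, _ = np.histogram2d(y_nm[mask], x_nm[mask], bins=(ye, xe))
        return h

    ref = hist(seg_of == 0)
    n_dims = 3 if axial else 2
    offsets = np.zeros((n_seg, n_dims))
    valid = np.ones(n_seg, dtype=bool)
    for s in range(1, n_seg):
        mask = seg_of == s
        if mask.sum() < min_locs:
            valid[s] = False
            continue
        dyx = _xcorr_offset(ref, hist(mask)) * bin_size_nm
        offsets[s, 0], offsets[s, 1] = dyx[1], dyx[0]  # store as (dx, dy)
        if axial:
            z = df["z"].to_numpy()
            offsets[s, 2] = np.median(z[mask]) - np.median(z[seg_of == 0])
    if not valid.all():
        warnings.warn(f"{(~valid).sum()} drift segment(s) too sparse; interpolated")
        good = np.where(valid)[0]
        for d in range(n_dims):
            offsets[~valid, d] = np.interp(np.where(~valid)[0], good, offsets[good, d])

    centres = np.minimum(np.arange(n_seg) * segment_frames + segment_frames / 2.0,
                         table.n_frames - 0.5)
    per_frame = np.stack([np.interp(frames, centres, offsets[:, d])
                          for d in range(n_dims)], axis=1)
    df["x"] = df["x"] - per_frame[:, 0] / a
    df["y"] = df["y"] - per_frame[:, 1] / a
    if axial:
        df["z"] = df["z"] - per_frame[:, 2]
    corrected = LocalizationTable(df, a, table.geometry_id, table.n_frames)
    return corrected, DriftTrace(offsets, segment_frames)


def rescale_z(table: LocalizationTable, factor: float = Z_RESCALE_FACTOR) -> LocalizationTable:
    """Multiply fitted z by ``factor`` (spherical-aberration correction)."""
    df = table.df.copy()
    df["z"] = df["z"] * factor
    out = LocalizationTable(df, table.pixel_size_nm, table.geometry_id, table.n_frames)
    out.z_rescale_factor = factor
    return out


def render(table: LocalizationTable, bin_size_nm: float, mode: str = "hist",
           sigma_nm: float | None = None, extent_nm=None) -> np.ndarray:
    """Render localizations into a super-resolution image.

    ``hist`` mode counts localizations per bin; ``gaussian`` mode adds a unit
    Gaussian blob per localization with width ``sigma_nm`` (default: the
    localization's own fitted sigma, falling back to one bin).
    """
    if bin_size_nm <= 0:
        raise ConfigurationError("bin size must be positive")
    if mode not in ("hist", "gaussian"):
        raise ConfigurationError(f"unknown render mode {mode!r}")
    a = table.pixel_size_nm
    x = table.df["x"].to_numpy() * a
    y = table.df["y"].to_numpy() * a
    if len(x) == 0:
        return np.zeros((1, 1))
    if extent_nm is None:
        x0, x1 = x.min(), x.max() + bin_size_nm
        y0, y1 = y.min(), y.max() + bin_size_nm
    else:
        (x0, x1), (y0, y1) = extent_nm
    xe = np.arange(x0, x1 + bin_size_nm, bin_size_nm)
    ye = np.arange(y0, y1 + bin_size_nm, bin_size_nm)
    if mode == "hist":
        img, _, _ = np.histogram2d(y, x, bins=(ye, xe))
        return img
    img = np.zeros((len(ye) - 1, len(xe) - 1))
    sig = table.df["sigma"].to_numpy()
    for xi, yi, si in zip(x, y, sig):
        s = sigma_nm if sigma_nm is not None else (si if np.isfinite(si) else bin_size_nm)
        s = max(s, 1e-6)
        gi = (yi - y0) / bin_size_nm - 0.5
        gj = (xi - x0) / bin_size_nm - 0.5
        half = max(int(np.ceil(3 * s / bin_size_nm)), 1)
        ii = np.arange(max(int(gi) - half, 0), min(int(gi) + half + 1, img.shape[0]))
        jj = np.arange(max(int(gj) - half, 0), min(int(gj) + half + 1, img.shape[1]))
        if len(ii) == 0 or len(jj) == 0:
            continue
        gy = np.exp(-((ii - gi) ** 2) * bin_size_nm**2 / (2 * s**2))
        gx = np.exp(-((jj - gj) ** 2) * bin_size_nm**2 / (2 * s**2))
        blob = np.outer(gy, gx)
        img[np.ix_(ii, jj)] += blob / blob.sum()
    return img
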