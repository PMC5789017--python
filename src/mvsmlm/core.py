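"""Core domain types and photo-electron conversion.

The pipeline works in two unit systems: raw camera counts (ADU) and
photo-electrons (e-).  A :class:`CameraCalibration` holds the per-pixel maps
needed to convert between them under the standard sCMOS noise model, in which
each pixel has its own baseline offset, gain and read-noise variance and the
total variance of a corrected pixel is (Poisson mean + read variance).

Fitted emitters are collected in a :class:`LocalizationTable`, a thin wrapper
around a :class:`pandas.DataFrame` plus acquisition metadata (pixel size,
plane-geometry id, movie length).  All positions are stored in the reference
camera's pixel frame, 0-based, with x running along columns and y along rows;
a localization at the center of pixel ``(i, j)`` has ``x == j`` and
``y == i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CalibrationError, ConfigurationError

#: Allowed values of the per-localization status field.
STATUS_CONVERGED = "converged"
STATUS_FAILED = "failed"
STATUS_REJECTED = "rejected"
STATUS_VALUES = (STATUS_CONVERGED, STATUS_FAILED, STATUS_REJECTED)

#: Scalar columns every localization table carries, in canonical order.
TABLE_COLUMNS = ("x", "y", "z", "photons", "background", "sigma", "frame", "status")


@dataclass(frozen=True)
class CameraCalibration:
    """Per-pixel sCMOS calibration: offset (ADU), gain (ADU/e-), read variance (e-^2).

    Scalar values are broadcast to full maps so that per-camera scalar
    calibrations and fully mapped calibrations go through the same code path.
    """

    offset_map: np.ndarray
    gain_map: np.ndarray
    readvar_map: np.ndarray

    def __post_init__(self):
        off = np.atleast_2d(np.asarray(self.offset_map, dtype=float))
        gain = np.asarray(self.gain_map, dtype=float)
        rv = np.asarray(self.readvar_map, dtype=float)
        gain = np.broadcast_to(gain, off.shape).copy() if gain.ndim < 2 else gain
        rv = np.broadcast_to(rv, off.shape).copy() if rv.ndim < 2 else rv
        if not (off.shape == gain.shape == rv.shape):
            raise ConfigurationError(
                f"calibration maps disagree in shape: offset {off.shape}, "
                f"gain {gain.shape}, readvar {rv.shape}"
            )
        if not np.all(gain > 0):
            raise CalibrationError("gain map must be strictly positive everywhere")
        if not np.all(rv >= 0):
            raise CalibrationError("read-noise variance map must be non-negative")
        object.__setattr__(self, "offset_map", off)
        object.__setattr__(self, "gain_map", gain)
        object.__setattr__(self, "readvar_map", rv)

    @property
    def shape(self) -> tuple[int, int]:
        return self.offset_map.shape

    @classmethod
    def from_scalars(cls, shape, offset: float, gain: float, readvar: float) -> "CameraCalibration":
        """Build a spatially uniform calibration (scalar per-camera values)."""
        shape = tuple(shape)
        return cls(
            offset_map=np.full(shape, float(offset)),
            gain_map=np.full(shape, float(gain)),
            readvar_map=np.full(shape, float(readvar)),
        )


UNITS_ADU = "adu"
UNITS_PHOTOELECTRONS = "photoelectrons"


@dataclass
class FrameStack:
    """A movie from one camera: (frame, row, col) pixels plus a units flag."""

    pixels: np.ndarray
    units: str = UNITS_ADU
    camera_id: str = "cam0"

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            px = px[None]
        if px.ndim != 3:
            raise ConfigurationError(f"movie must be 3D (frame,row,col), got ndim={px.ndim}")
        if self.units not in (UNITS_ADU, UNITS_PHOTOELECTRONS):
            raise ConfigurationError(f"unknown units flag {self.units!r}")
        if self.units == UNITS_ADU:
            if np.issubdtype(px.dtype, np.floating):
                if np.any(px < 0) or not np.allclose(px, np.round(px)):
                    raise ConfigurationError("raw ADU frames must be non-negative integers")
                px = px.astype(np.uint16)
            elif np.any(px < 0):
                raise ConfigurationError("raw ADU frames must be non-negative")
        else:
            px = np.asarray(px, dtype=float)
            if not np.all(np.isfinite(px)):
                raise ConfigurationError("corrected frames must be finite")
        self.pixels = px

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]


@dataclass
class Localization:
    """A single fitted emitter in reference-camera pixel coordinates."""

    x: float
    y: float
    z: float = 0.0
    photons: float = 0.0
    background: float = 0.0
    sigma: float = np.nan  # Gaussian width in nm; NaN for spline fits
    frame: int = 0
    plane_signals: tuple = ()
    status: str = STATUS_CONVERGED

    def __post_init__(self):
        if self.status not in STATUS_VALUES:
            raise ConfigurationError(f"invalid status {self.status!r}")


class LocalizationTable:
    """Ordered collection of localizations plus acquisition metadata.

    Parameters
    ----------
    df : pandas.DataFrame
        Must contain :data:`TABLE_COLUMNS`; any ``signal<p>`` columns hold the
        per-plane fitted signals.
    pixel_size_nm : float
        Back-projected pixel size of the reference camera, in nm.
    geometry_id : str
        Identifier of the plane geometry used for fitting.
    n_frames : int
        Movie length; all frame indices must lie in ``[0, n_frames)``.
    """

    def __init__(self, df: pd.DataFrame, pixel_size_nm: float, geometry_id: str = "single",
                 n_frames: int | None = None):
        df = df.copy().reset_index(drop=True)
        for col in TABLE_COLUMNS:
            if col not in df.columns:
                raise ConfigurationError(f"localization table missing column {col!r}")
        if pixel_size_nm <= 0:
            raise ConfigurationError("pixel size must be positive")
        if n_frames is None:
            n_frames = int(df["frame"].max()) + 1 if len(df) else 0
        if len(df):
            fr = df["frame"].to_numpy()
            if fr.min() < 0 or fr.max() >= n_frames:
                raise ConfigurationError("frame indices must lie within [0, movie length)")
            bad = ~df["status"].isin(STATUS_VALUES)
            if bad.any():
                raise ConfigurationError(f"invalid status values: {df['status'][bad].unique()}")
        self.df = df
        self.pixel_size_nm = float(pixel_size_nm)
        self.geometry_id = str(geometry_id)
        self.n_frames = int(n_frames)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(cls, records: list[Localization], pixel_size_nm: float,
                     geometry_id: str = "single", n_frames: int | None = None) -> "LocalizationTable":
        n_planes = max((len(r.plane_signals) for r in records), default=0)
        rows = []
        for r in records:
            row = {c: getattr(r, c) for c in TABLE_COLUMNS}
            for p in range(n_planes):
                row[f"signal{p}"] = r.plane_signals[p] if p < len(r.plane_signals) else 0.0
            rows.append(row)
        df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS) + [f"signal{p}" for p in range(n_planes)])
        return cls(df, pixel_size_nm, geometry_id, n_frames)

    # -- access -----------------------------------------------------------
    @property
    def signal_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("signal")]

    @property
    def n_planes(self) -> int:
        return len(self.signal_columns)

    def plane_signals(self) -> np.ndarray:
        """(n, n_planes) array of per-plane fitted signals (e-)."""
        cols = self.signal_columns
        if not cols:
            return np.zeros((len(self.df), 0))
        return self.df[cols].to_numpy(dtype=float)

    def records(self) -> list[Localization]:
        out = []
        sig = self.plane_signals()
        for i, row in self.df.iterrows():
            out.append(Localization(
                x=row["x"], y=row["y"], z=row["z"], photons=row["photons"],
                background=row["background"], sigma=row["sigma"], frame=int(row["frame"]),
                plane_signals=tuple(sig[i]), status=row["status"]))
        return out

    def converged(self) -> "LocalizationTable":
        """Sub-table of converged fits only."""
        return LocalizationTable(self.df[self.df["status"] == STATUS_CONVERGED],
                                 self.pixel_size_nm, self.geometry_id, self.n_frames)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LocalizationTable):
            return NotImplemented
        meta = (self.pixel_size_nm == other.pixel_size_nm
                and self.geometry_id == other.geometry_id
                and self.n_frames == other.n_frames)
        if not meta or list(self.df.columns) != list(other.df.columns):
            return False
        try:
            pd.testing.assert_frame_equal(self.df, other.df, check_dtype=False)
        except AssertionError:
            return False
        return True


def correct_frames(raw: FrameStack, cal: CameraCalibration) -> FrameStack:
    """Convert a raw ADU movie to photo-electrons: ``(raw - offset) / gain``.

    Negative outputs are kept: read noise can undershoot the offset, and
    clipping at zero would bias the downstream MLE.
    """
    if raw.units != UNITS_ADU:
        raise ConfigurationError("correct_frames expects a raw ADU stack")
    if raw.frame_shape != cal.shape:
        raise ConfigurationError(
            f"frame shape {raw.frame_shape} does not match calibration shape {cal.shape}")
    corrected = (raw.pixels.astype(float) - cal.offset_map[None]) / cal.gain_map[None]
    return FrameStack(pixels=corrected, units=UNITS_PHOTOELECTRONS, camera_id=raw.camera_id)
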