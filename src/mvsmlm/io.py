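"""File I/O: TIFF movies, HDF5 localization tables / calibrations / PSF models.

Movies travel as multi-page TIFF (16-bit unsigned for raw ADU, float32 for
corrected photo-electron stacks).  Everything else lives in HDF5 with a small
amount of self-describing metadata, plus a flat CSV export for tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .core import (UNITS_ADU, UNITS_PHOTOELECTRONS, CameraCalibration,
                   FrameStack, LocalizationTable, TABLE_COLUMNS)
from .errors import ParseError

_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------

def write_movie(stack: FrameStack, path) -> None:
    path = Path(path)
    px = stack.pixels
    if stack.units == UNITS_ADU:
        px = px.astype(np.uint16)
    else:
        px = px.astype(np.float32)
    tifffile.imwrite(path, px, photometric="minisblack",
                     metadata={"units": stack.units, "camera_id": stack.camera_id})


def read_movie(path) -> FrameStack:
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            px = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    except (tifffile.TiffFileError, ValueError, OSError) as exc:
        raise ParseError(f"cannot read movie {path}: {exc}") from exc
    if px.ndim == 2:
        px = px[None]
    units = meta.get("units", UNITS_ADU if px.dtype.kind == "u" else UNITS_PHOTOELECTRONS)
    return FrameStack(pixels=px, units=units, camera_id=meta.get("camera_id", "cam0"))


# ---------------------------------------------------------------------------
# localization tables
# ---------------------------------------------------------------------------

def write_table(table: LocalizationTable, path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["content"] = "localization_table"
        f.attrs["pixel_size_nm"] = table.pixel_size_nm
        f.attrs["geometry_id"] = table.geometry_id
        f.attrs["n_frames"] = table.n_frames
        g = f.create_group("locs")
        for col in TABLE_COLUMNS:
            data = table.df[col].to_numpy()
            if col == "status":
                data = data.astype("S12")
            g.create_dataset(col, data=data)
        planes = f.create_group("planes")
        for p, col in enumerate(table.signal_columns):
            planes.create_group(f"plane{p}").create_dataset(
                "signal", data=table.df[col].to_numpy(dtype=float))


def read_table(path) -> LocalizationTable:
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("content") != "localization_table":
                raise ParseError(f"{path} is not a localization table")
            cols = {}
            for col in TABLE_COLUMNS:
                if col not in f["locs"]:
                    raise ParseError(f"{path}: missing field {col!r}")
                data = f["locs"][col][()]
                if col == "status":
                    data = np.array([s.decode() for s in data])
                cols[col] = data
            df = pd.DataFrame(cols)
            if "planes" in f:
                for p in range(len(f["planes"])):
                    df[f"signal{p}"] = f[f"planes/plane{p}/signal"][()]
            return LocalizationTable(df, float(f.attrs["pixel_size_nm"]),
                                     str(f.attrs["geometry_id"]), int(f.attrs["n_frames"]))
    except (OSError, KeyError) as exc:
        raise ParseError(f"cannot read table {path}: {exc}") from exc


def export_table_csv(table: LocalizationTable, path) -> None:
    """Flat CSV export; per-plane signals are ';'-joined in a plane_signals column."""
    df = table.df[list(TABLE_COLUMNS)].copy()
    sig = table.plane_signals()
    df["plane_signals"] = [";".join(f"{v:.6g}" for v in row) for row in sig]
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# camera calibrations
# ---------------------------------------------------------------------------

def write_calibration(cal: CameraCalibration, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["content"] = "camera_calibration"
        f.create_dataset("offset_map", data=cal.offset_map)
        f.create_dataset("gain_map", data=cal.gain_map)
        f.create_dataset("readvar_map", data=cal.readvar_map)


def read_calibration(path) -> CameraCalibration:
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("content") != "camera_calibration":
                raise ParseError(f"{path} is not a camera calibration")
            return CameraCalibration(f["offset_map"][()], f["gain_map"][()],
                                     f["readvar_map"][()])
    except (OSError, KeyError) as exc:
        raise ParseError(f"cannot read calibration {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# affine transforms (JSON: 6 numbers + direction tag)
# ---------------------------------------------------------------------------

def write_transform(transform, path) -> None:
    from .register import AffineTransform2D  # local import avoids a cycle
    assert isinstance(transform, AffineTransform2D)
    payload = {
        "format_version": _FORMAT_VERSION,
        "content": "affine_transform_2d",
        "direction": "secondary_to_reference",
        "linear": transform.linear.ravel().tolist(),
        "translation": transform.translation.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_transform(path):
    from .register import AffineTransform2D
    try:
        payload = json.loads(Path(path).read_text())
        if payload.get("content") != "affine_transform_2d":
            raise ParseError(f"{path} is not an affine transform")
        return AffineTransform2D(np.array(payload["linear"], dtype=float).reshape(2, 2),
                                 np.array(payload["translation"], dtype=float))
    except (OSError, ValueError, KeyError) as exc:
        raise ParseError(f"cannot read transform {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# spline PSF models
# ---------------------------------------------------------------------------

def write_spline_psf(psf, path) -> None:
    from .psf import SplinePSF
    assert isinstance(psf, SplinePSF)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["content"] = "spline_psf"
        f.attrs["z_min"] = psf.z_min
        f.attrs["z_step"] = psf.z_step
        f.attrs["normalization"] = psf.normalization
        f.create_dataset("coefficients", data=psf.coefficients)
        f.create_dataset("stack", data=psf.stack)


def read_spline_psf(path):
    from .psf import SplinePSF
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("content") != "spline_psf":
                raise ParseError(f"{path} is not a spline PSF")
            return SplinePSF(stack=f["stack"][()], z_min=float(f.attrs["z_min"]),
                             z_step=float(f.attrs["z_step"]),
                             normalization=float(f.attrs["normalization"]),
                             _coefficients=f["coefficients"][()])
    except (OSError, KeyError) as exc:
        raise ParseError(f"cannot read spline PSF {path}: {exc}") from exc
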