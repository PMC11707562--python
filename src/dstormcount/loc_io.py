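"""Localization-table and image-stack I/O with unit normalization.

All coordinates are held internally in nanometers in the sample plane and
frame indices are 0-based.  Two table dialects are supported:

``csv``
    Plain-text table with header ``frame,x_nm,y_nm,photons,precision_nm``.
    The header declares the units: columns named ``x``/``y`` (without the
    ``_nm`` suffix) are interpreted as camera pixels and scaled by
    ``pixel_size_nm`` on read.

``hdf5-table``
    One HDF5 group ``locs`` holding one dataset per column with a ``units``
    attribute (``'nm'`` or ``'px'``) and acquisition metadata
    (``pixel_size_nm``, ``n_frames``, ``exposure_ms``) as attributes.
    The writer emits nanometer coordinates so that write -> read round-trips
    are bit-exact; pixel-unit files written by other SMLM software are
    converted on read.

Image stacks (confocal z-stacks, rendered images) are multi-page TIFF read
through :mod:`tifffile`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .exceptions import ConfigurationError, FormatError, ParseError

#: default camera pixel size of the dSTORM setup, nm
DEFAULT_PIXEL_SIZE_NM = 107.0
#: default acquisition length, frames
DEFAULT_N_FRAMES = 30_000
#: default exposure time, ms
DEFAULT_EXPOSURE_MS = 30.0
#: sigma substituted when a table carries no precision column, nm
DEFAULT_PRECISION_NM = 10.0

LOC_COLUMNS = ("frame", "x", "y", "photons", "precision", "id")
_CSV_HEADER = ("frame", "x_nm", "y_nm", "photons", "precision_nm", "id")


@dataclass
class LocalizationTable:
    """One dSTORM acquisition as a table of single-emitter localizations.

    ``records`` is a DataFrame with columns ``frame`` (int, 0-based),
    ``x``/``y`` (nm), ``photons``, ``precision`` (nm) and ``id`` (row
    identity, int).
    """

    records: pd.DataFrame
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    n_frames: int = DEFAULT_N_FRAMES
    exposure_ms: float = DEFAULT_EXPOSURE_MS

    def __post_init__(self) -> None:
        df = self.records
        if len(df) == 0 and set(LOC_COLUMNS) - set(df.columns):
            df = pd.DataFrame({c: pd.Series(dtype=float) for c in LOC_COLUMNS})
        df = df.copy()
        if "photons" not in df:
            df["photons"] = 0.0
        if "precision" not in df:
            warnings.warn(
                "table has no precision column; filling with "
                f"{DEFAULT_PRECISION_NM} nm",
                stacklevel=2,
            )
            df["precision"] = DEFAULT_PRECISION_NM
        if "id" not in df:
            df["id"] = np.arange(len(df), dtype=np.int64)
        df["frame"] = df["frame"].astype(np.int64)
        df["id"] = df["id"].astype(np.int64)
        for c in ("x", "y", "photons", "precision"):
            df[c] = df[c].astype(np.float64)
        self.records = df[list(LOC_COLUMNS)].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.records
        if len(df) == 0:
            return
        if (df["frame"] < 0).any():
            raise ValueError("frame indices must be >= 0")
        if (df["frame"] >= self.n_frames).any():
            raise ValueError("frame index beyond n_frames")
        if (df["precision"] <= 0).any():
            raise ValueError("precision must be > 0")
        if (df["photons"] < 0).any():
            raise ValueError("photons must be >= 0")

    def __len__(self) -> int:
        return len(self.records)

    def sorted_by_frame(self) -> "LocalizationTable":
        """Copy with records stably sorted by frame (the write order)."""
        df = self.records.sort_values("frame", kind="stable").reset_index(drop=True)
        return LocalizationTable(
            df, self.pixel_size_nm, self.n_frames, self.exposure_ms
        )


def _coerce_numeric(df: pd.DataFrame, column: str, path) -> pd.Series:
    out = pd.to_numeric(df[column], errors="coerce")
    bad = out.isna() & df[column].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: non-numeric value {df[column].iloc[row]!r} in column "
            f"{column!r} at data row {row}"
        )
    if out.isna().any():
        row = int(np.flatnonzero(out.isna().to_numpy())[0])
        raise ParseError(f"{path}: missing value in column {column!r} at data row {row}")
    # numpy's str->float64 conversion is correctly rounded (pd.to_numeric is
    # only used above to locate unparseable rows)
    return pd.Series(df[column].to_numpy(dtype=np.float64), index=df.index)


def read_localizations(
    path,
    dialect: str = "csv",
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    n_frames: int = DEFAULT_N_FRAMES,
    exposure_ms: float = DEFAULT_EXPOSURE_MS,
    default_precision_nm: float = DEFAULT_PRECISION_NM,
) -> LocalizationTable:
    """Read a localization table, normalizing coordinates to nm.

    Parameters
    ----------
    path : str or Path
        File to read.
    dialect : {'csv', 'hdf5-table'}
        On-disk format (see module docstring).
    pixel_size_nm : float
        Camera pixel size used to convert pixel-unit coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        return _read_csv(path, pixel_size_nm, n_frames, exposure_ms, default_precision_nm)
    if dialect == "hdf5-table":
        return _read_hdf5(path, pixel_size_nm, n_frames, exposure_ms, default_precision_nm)
    raise ConfigurationError(f"unknown localization dialect {dialect!r}")


def _read_csv(path, pixel_size_nm, n_frames, exposure_ms, default_precision_nm):
    raw = pd.read_csv(path, dtype=str)
    cols = {c.strip(): c for c in raw.columns}
    if "frame" not in cols:
        raise ParseError(f"{path}: missing required column 'frame'")
    in_px = "x" in cols and "x_nm" not in cols
    xcol = cols.get("x_nm", cols.get("x"))
    ycol = cols.get("y_nm", cols.get("y"))
    if xcol is None or ycol is None:
        raise ParseError(f"{path}: missing coordinate columns")
    df = pd.DataFrame()
    df["frame"] = _coerce_numeric(raw, cols["frame"], path).astype(np.int64)
    scale = pixel_size_nm if in_px else 1.0
    df["x"] = _coerce_numeric(raw, xcol, path) * scale
    df["y"] = _coerce_numeric(raw, ycol, path) * scale
    if "photons" in cols:
        df["photons"] = _coerce_numeric(raw, cols["photons"], path)
    pcol = cols.get("precision_nm", cols.get("precision"))
    if pcol is not None:
        df["precision"] = _coerce_numeric(raw, pcol, path)
    else:
        df["precision"] = default_precision_nm
        warnings.warn(f"{path}: no precision column; using {default_precision_nm} nm")
    if "id" in cols:
        df["id"] = _coerce_numeric(raw, cols["id"], path).astype(np.int64)
    return LocalizationTable(df, pixel_size_nm, n_frames, exposure_ms)


def _read_hdf5(path, pixel_size_nm, n_frames, exposure_ms, default_precision_nm):
    with h5py.File(path, "r") as fh:
        if "locs" not in fh:
            raise FormatError(f"{path}: no 'locs' group")
        grp = fh["locs"]
        units = grp.attrs.get("units", "nm")
        pixel_size_nm = float(grp.attrs.get("pixel_size_nm", pixel_size_nm))
        n_frames = int(grp.attrs.get("n_frames", n_frames))
        exposure_ms = float(grp.attrs.get("exposure_ms", exposure_ms))
        data = {}
        for col in LOC_COLUMNS:
            if col in grp:
                data[col] = np.asarray(grp[col])
    if "frame" not in data or "x" not in data or "y" not in data:
        raise FormatError(f"{path}: hdf5 table lacks frame/x/y datasets")
    if units == "px":
        data["x"] = data["x"] * pixel_size_nm
        data["y"] = data["y"] * pixel_size_nm
    elif units != "nm":
        raise FormatError(f"{path}: unknown units attribute {units!r}")
    df = pd.DataFrame(data)
    if "precision" not in df:
        df["precision"] = default_precision_nm
        warnings.warn(f"{path}: no precision dataset; using {default_precision_nm} nm")
    return LocalizationTable(df, pixel_size_nm, n_frames, exposure_ms)


def write_localizations(table: LocalizationTable, path, dialect: str = "csv") -> None:
    """Write ``table`` sorted ascending by frame; lossless round-trip."""
    path = Path(path)
    table = table.sorted_by_frame()
    df = table.records
    if dialect == "csv":
        out = df.rename(
            columns={"x": "x_nm", "y": "y_nm", "precision": "precision_nm"}
        )[list(_CSV_HEADER)]
        out.to_csv(path, index=False)
    elif dialect == "hdf5-table":
        with h5py.File(path, "w") as fh:
            grp = fh.create_group("locs")
            for col in LOC_COLUMNS:
                grp.create_dataset(col, data=df[col].to_numpy())
            grp.attrs["units"] = "nm"
            grp.attrs["pixel_size_nm"] = table.pixel_size_nm
            grp.attrs["n_frames"] = table.n_frames
            grp.attrs["exposure_ms"] = table.exposure_ms
    else:
        raise ConfigurationError(f"unknown localization dialect {dialect!r}")


def read_stack(path) -> np.ndarray:
    """Read a (possibly multi-page) TIFF as a z × rows × cols photon-count array."""
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # tifffile raises assorted types on bad input
        raise FormatError(f"{path}: not a readable TIFF stack ({exc})") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a 2D image or 3D stack, got ndim={arr.ndim}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise FormatError(f"{path}: photon-count stack must be integer-valued")
        arr = np.round(arr).astype(np.int64)
    return arr


def write_stack(stack: np.ndarray, path) -> None:
    """Write an integer stack as a multi-page 16-bit TIFF."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.min() < 0 or stack.max() > np.iinfo(np.uint16).max:
        raise ValueError("stack values outside uint16 range")
    tifffile.imwrite(Path(path), stack.astype(np.uint16))
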