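"""Recording readers/writers (CSV and HDF5) and small table writers.

CSV recordings have a time column (seconds or ISO timestamps) and a
pressure column (mmHg).  HDF5 recordings use a ``/pressure`` dataset
with ``fs`` and ``id`` attributes (a ``/time`` dataset, if present, is
validated the same way as the CSV time column).  Internally everything
is sample index + sampling rate; timestamps only establish ``fs`` and
uniformity.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import Recording

__all__ = ["read_recording", "write_recording"]

log = logging.getLogger(__name__)

_TIME_NAMES = ("time", "timestamp", "t", "time_s")
_PRESSURE_NAMES = ("pressure", "icp", "icp_mmhg", "value")

#: allowed deviation of any sampling interval from the nominal 1/fs,
#: as a fraction of 1/fs
_JITTER_TOL = 0.1


def _pick_column(df: pd.DataFrame, names: tuple[str, ...], fallback: int) -> str:
    for c in df.columns:
        if str(c).strip().lower() in names:
            return c
    return df.columns[fallback]


def _times_to_seconds(t: pd.Series) -> np.ndarray:
    if np.issubdtype(t.dtype, np.number):
        return t.to_numpy(dtype=float)
    ts = pd.to_datetime(t, errors="raise")
    return (ts - ts.iloc[0]).dt.total_seconds().to_numpy()


def _fs_from_times(tsec: np.ndarray, n: int) -> tuple[float, np.ndarray | None]:
    """Infer fs; return (fs, resample_grid or None)."""
    dt = np.diff(tsec)
    if np.any(dt <= 0):
        raise ValueError("time column must be strictly increasing")
    nominal = float(np.median(dt))
    fs = 1.0 / nominal
    if np.max(np.abs(dt - nominal)) > _JITTER_TOL * nominal:
        warnings.warn(
            "non-uniform sampling beyond tolerance; resampling onto a uniform grid",
            stacklevel=3,
        )
        grid = tsec[0] + np.arange(n) * nominal
        return fs, grid
    return fs, None


def _check_nans(x: np.ndarray, fs: float, max_gap_s: float) -> np.ndarray:
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    # longest NaN run
    idx = np.flatnonzero(bad)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    longest = max(len(r) for r in runs)
    if longest > max_gap_s * fs:
        raise ValueError(
            f"NaN run of {longest} samples exceeds the {max_gap_s:g} s imputation window"
        )
    warnings.warn(f"{bad.sum()} missing samples linearly interpolated", stacklevel=3)
    x = x.copy()
    good = ~bad
    x[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(good), x[good])
    return x


def read_recording(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
    max_nan_gap_s: float = 10.0,
) -> Recording:
    """Load a recording from CSV or HDF5.

    ``format`` is inferred from the extension when omitted.  For CSV,
    ``fs`` overrides time-column inference.  Non-monotone time, missing
    columns, and NaN runs longer than ``max_nan_gap_s`` raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("hdf5" if path.suffix.lower() in (".h5", ".hdf5", ".hdf") else "csv")
    if fmt == "csv":
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        if df.shape[1] < 2 and fs is None:
            raise ValueError(f"{path}: need time + pressure columns or an explicit fs")
        pcol = _pick_column(df, _PRESSURE_NAMES, fallback=min(1, df.shape[1] - 1))
        x = df[pcol].to_numpy(dtype=float)
        if fs is None:
            tcol = _pick_column(df, _TIME_NAMES, fallback=0)
            if tcol == pcol:
                raise ValueError(f"{path}: cannot identify distinct time and pressure columns")
            tsec = _times_to_seconds(df[tcol])
            fs, grid = _fs_from_times(tsec, len(x))
            if grid is not None:
                x = np.interp(grid, tsec, x)
        x = _check_nans(x, fs, max_nan_gap_s)
        return Recording(samples=x, fs=fs, id=path.stem)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "pressure" not in f:
                raise ValueError(f"{path}: missing /pressure dataset")
            x = f["pressure"][:].astype(float)
            file_fs = f["pressure"].attrs.get("fs", f.attrs.get("fs"))
            rid = f["pressure"].attrs.get("id", path.stem)
            if isinstance(rid, bytes):
                rid = rid.decode()
            if "time" in f:
                tsec = f["time"][:].astype(float)
                inferred, grid = _fs_from_times(tsec, len(x))
                if grid is not None:
                    x = np.interp(grid, tsec, x)
                file_fs = file_fs if file_fs is not None else inferred
            if fs is None:
                if file_fs is None:
                    raise ValueError(f"{path}: no fs attribute and no /time dataset")
                fs = float(file_fs)
        x = _check_nans(x, fs, max_nan_gap_s)
        return Recording(samples=x, fs=fs, id=str(rid))
    raise ValueError(f"unknown format {fmt!r}; use 'csv' or 'hdf5'")


def write_recording(recording: Recording, path: str | Path, format: str | None = None) -> Path:
    """Write a recording as CSV (time, pressure) or HDF5 (/pressure)."""
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix.lower() in (".h5", ".hdf5", ".hdf") else "csv")
    if fmt == "csv":
        df = pd.DataFrame({"time": recording.time, "pressure": recording.samples})
        df.to_csv(path, index=False)
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            d = f.create_dataset("pressure", data=recording.samples)
            d.attrs["fs"] = recording.fs
            d.attrs["id"] = recording.id
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'csv' or 'hdf5'")
    return path
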