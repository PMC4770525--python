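"""Readers and writers for device recordings and pipeline configuration.

Two on-disk formats are supported:

* ``csv`` -- human-readable text with mandatory header
  ``time_s,pressure_kpa,i520,i640,i950,temp_c``; numbers are written with 6
  significant digits and missing values as empty fields.
* ``hdf5`` -- lossless single-file container with datasets ``/time``,
  ``/pressure``, ``/i520``, ``/i640``, ``/i950``, ``/temp``, a root attribute
  ``sample_rate_hz`` and metadata under ``meta/*``; write->read round-trips
  are bit-exact.

Configuration files are YAML mirroring :class:`~crtpipe.datamodel.PipelineConfig`
field names exactly.
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .datamodel import WAVELENGTHS, DeviceRecording, PipelineConfig
from .errors import ConfigError, SchemaError

CSV_COLUMNS = ["time_s", "pressure_kpa", "i520", "i640", "i950", "temp_c"]

_H5_DATASETS = {
    "time": "time",
    "pressure": "pressure",
    "i520": "i520",
    "i640": "i640",
    "i950": "i950",
    "temp": "temp",
}


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    return "csv"


def _infer_sample_rate(time: np.ndarray) -> float:
    if len(time) < 2:
        return 62.04  # nominal optical rate; irrelevant for <2 samples
    return 1.0 / float(np.median(np.diff(time)))


def read_recording(path: str | Path, format: str | None = None) -> DeviceRecording:
    """Read a :class:`DeviceRecording`, validating all invariants.

    Raises :class:`SchemaError` naming the offending column/row on a
    malformed header, non-uniform time grid or missing channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "hdf5":
        return _read_hdf5(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_recording(rec: DeviceRecording, path: str | Path, format: str | None = None) -> None:
    """Write a recording; the result is readable by :func:`read_recording`."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        _write_csv(rec, path)
    elif fmt == "hdf5":
        _write_hdf5(rec, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _read_csv(path: Path) -> DeviceRecording:
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed beyond repair
        raise SchemaError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} in header {list(df.columns)}")
    for c in CSV_COLUMNS:
        if len(df) and not np.issubdtype(df[c].dtype, np.number):
            bad = df.index[pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()]
            row = int(bad[0]) + 1 if len(bad) else "?"
            raise SchemaError(f"{path}: non-numeric value in column {c!r} at row {row}")
    time = df["time_s"].to_numpy(float)
    meta = _read_csv_meta(path)
    sr = float(meta.pop("sample_rate_hz", 0) or 0) or _infer_sample_rate(time)
    return DeviceRecording(
        time=time,
        pressure=df["pressure_kpa"].to_numpy(float),
        intensity={w: df[f"i{w}"].to_numpy(float) for w in WAVELENGTHS},
        temperature=df["temp_c"].to_numpy(float),
        sample_rate=sr,
        meta=meta,
    )


def _read_csv_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


def _write_csv(rec: DeviceRecording, path: Path) -> None:
    # data channels at 6 significant digits; time at full precision so the
    # 1-ppm uniform-grid invariant survives the round trip on long sessions
    df = pd.DataFrame(
        {
            "time_s": [f"{v:.12g}" for v in rec.time],
            "pressure_kpa": rec.pressure,
            "i520": rec.intensity[520],
            "i640": rec.intensity[640],
            "i950": rec.intensity[950],
            "temp_c": rec.temperature,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz = {rec.sample_rate!r}\n")
        for k, v in rec.meta.items():
            fh.write(f"# {k} = {v}\n")
        df.to_csv(fh, index=False, float_format="%.6g", na_rep="")


def _read_hdf5(path: Path) -> DeviceRecording:
    with h5py.File(path, "r") as f:
        for name in _H5_DATASETS.values():
            if name not in f:
                raise SchemaError(f"{path}: missing dataset /{name}")
        meta = {}
        if "meta" in f:
            meta = {k: str(v) for k, v in f["meta"].attrs.items()}
        return DeviceRecording(
            time=f["time"][:],
            pressure=f["pressure"][:],
            intensity={w: f[f"i{w}"][:] for w in WAVELENGTHS},
            temperature=f["temp"][:],
            sample_rate=float(f.attrs["sample_rate_hz"]),
            meta=meta,
        )


def _write_hdf5(rec: DeviceRecording, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("time", data=rec.time)
        f.create_dataset("pressure", data=rec.pressure)
        for w in WAVELENGTHS:
            f.create_dataset(f"i{w}", data=rec.intensity[w])
        f.create_dataset("temp", data=rec.temperature)
        f.attrs["sample_rate_hz"] = rec.sample_rate
        g = f.create_group("meta")
        for k, v in rec.meta.items():
            g.attrs[k] = str(v)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML (unknown keys rejected)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    return PipelineConfig.from_dict(data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
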