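"""Core domain types for automated capillary refill time (CRT) analysis.

A *recording* is a synchronized set of uniformly sampled channels produced by
the CRT datalogger: pneumatic cuff pressure (kPa), diffuse-reflectance optical
intensity in ADC counts at three LED wavelengths (520, 640 and 950 nm), and
skin-surface temperature (degC).  All channels are stored on the optical
sample grid (nominally 62.04 Hz, one sample per demodulator DFT bin); real
hardware may subsample the pressure/temperature channels, in which case they
are expected to be upsampled onto the optical grid before ingest.

Time is 0-based seconds from the start of the recording; a wall-clock start
time, if known, lives in ``meta`` so absolute timestamps can be reconstructed
additively.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigError, SchemaError

#: The LED wavelengths of the reflectance sensor, in nanometres.
WAVELENGTHS = (520, 640, 950)

#: Exact conversion factor from mmHg to kPa.
MMHG_TO_KPA = 0.1333224

#: Relative tolerance for the uniform-time-grid invariant.
GRID_RTOL = 1e-6


def mmhg_to_kpa(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to kPa.

    The cuff applies 130 mmHg (~17 kPa), chosen to exceed systolic blood
    pressure so the capillary bed blanches reliably.

    >>> round(mmhg_to_kpa(130))
    17
    """
    if not np.all(np.isfinite(p_mmhg)):
        raise ValueError("pressure must be finite")
    return p_mmhg * MMHG_TO_KPA


@dataclass
class DeviceRecording:
    """Synchronized multi-channel time series from the CRT device.

    Parameters
    ----------
    time:
        Seconds since recording start, strictly increasing, uniform to within
        one part in 10^6.
    pressure:
        Cuff air pressure in kPa, non-negative where finite.
    intensity:
        Mapping wavelength (nm) -> ADC counts, non-negative where finite.
        Missing samples are NaN, never zero.
    temperature:
        Skin-surface temperature in degC (NaN for missing samples).
    sample_rate:
        Samples per second; must match the time grid.
    meta:
        Free-text key/value metadata (subject id, session id, seed, ...).
    """

    time: np.ndarray
    pressure: np.ndarray
    intensity: dict[int, np.ndarray]
    temperature: np.ndarray
    sample_rate: float
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.intensity = {int(w): np.asarray(v, dtype=float) for w, v in self.intensity.items()}
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n = len(self.time)
        if self.sample_rate <= 0:
            raise SchemaError(f"sample_rate must be > 0, got {self.sample_rate}")
        for name, arr in self._channels():
            if len(arr) != n:
                raise SchemaError(
                    f"channel {name!r} has {len(arr)} samples, expected {n} (length of time)"
                )
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                row = int(np.argmax(dt <= 0)) + 1
                raise SchemaError(f"time not strictly increasing at row {row}")
            dt0 = 1.0 / self.sample_rate
            bad = np.abs(dt - dt0) > GRID_RTOL * dt0
            if np.any(bad):
                row = int(np.argmax(bad)) + 1
                raise SchemaError(
                    f"non-uniform time grid at row {row}: step {dt[bad][0]:.9g} s "
                    f"vs expected {dt0:.9g} s"
                )
        if np.any(self.pressure[np.isfinite(self.pressure)] < 0):
            row = int(np.flatnonzero(self.pressure < 0)[0])
            raise SchemaError(f"negative pressure at row {row}")
        for w, arr in self.intensity.items():
            if np.any(arr[np.isfinite(arr)] < 0):
                row = int(np.flatnonzero(arr < 0)[0])
                raise SchemaError(f"negative intensity (i{w}) at row {row}")

    def _channels(self):
        yield "pressure", self.pressure
        for w in sorted(self.intensity):
            yield f"i{w}", self.intensity[w]
        yield "temperature", self.temperature

    def __len__(self) -> int:
        return len(self.time)

    @property
    def duration_s(self) -> float:
        return float(self.time[-1] - self.time[0]) if len(self) else 0.0

    def copy(self) -> "DeviceRecording":
        return DeviceRecording(
            time=self.time.copy(),
            pressure=self.pressure.copy(),
            intensity={w: v.copy() for w, v in self.intensity.items()},
            temperature=self.temperature.copy(),
            sample_rate=self.sample_rate,
            meta=dict(self.meta),
        )


@dataclass
class RefillSegment:
    """One post-release optical window for a single wavelength.

    ``time_rel`` is seconds since the pressure release, starting at the first
    sample at/after the release (so ``time_rel[0]`` lies in [0, 1/fs)).
    """

    release_time_s: float
    time_rel: np.ndarray
    intensity: np.ndarray
    wavelength: int
    spot_temperature_c: float
    truncated: bool = False
    sample_rate: float = 62.04

    def __post_init__(self) -> None:
        self.time_rel = np.asarray(self.time_rel, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.time_rel) != len(self.intensity):
            raise SchemaError("segment time/intensity length mismatch")


@dataclass
class PipelineConfig:
    """Tunable parameters of the CRT extraction pipeline.

    Defaults follow the device's published processing chain: release detection
    uses a 3.5/3.1 kPa hysteresis pair with a >=1 s hold, refill windows are
    the 10 s after each release, the two-part fit transition is scanned over
    1-6 s, CRT is the 20% fractional-threshold crossing, refill-time series
    are resampled at 0.1 Hz and smoothed with a 2 mHz second-order
    forward-reverse Bessel filter.

    ``max_rms_error`` and ``max_baseline_slope`` have no published values
    (they were tuned by eye on the original data); the defaults here are
    calibrated against the built-in simulator (see docs/methods.md) and are
    logged with every run.
    """

    pressure_upper_kpa: float = 3.5
    pressure_lower_kpa: float = 3.1
    hold_min_s: float = 1.0
    window_s: float = 10.0
    transition_min_s: float = 1.0
    transition_max_s: float = 6.0
    threshold_level: float = 0.20
    max_rms_error: float = 12.5          # counts; simulator-calibrated
    max_baseline_slope: float = 10.0     # counts/s; ~1% of nominal baseline/s
    resample_hz: float = 0.1
    bessel_fc_hz: float = 0.002
    bessel_order: int = 2
    quality_window_s: float = 600.0
    # secondary/interpretation switches
    bessel_fc2_hz: float = 0.0005        # extra cascade stage used at 520 nm
    cascade_520: bool = True             # cascade (True) vs replace reading
    refill_slope_from_line: bool = False  # region-1 slope from separate line fit
    gap_max_s: float = 115.0             # bridge gaps up to 5 cycle periods

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold_level < 1.0):
            raise ConfigError(f"threshold_level must be in (0,1), got {self.threshold_level}")
        if not (self.pressure_lower_kpa < self.pressure_upper_kpa):
            raise ConfigError(
                "pressure_lower_kpa must be < pressure_upper_kpa "
                f"({self.pressure_lower_kpa} >= {self.pressure_upper_kpa})"
            )
        if not (self.transition_min_s < self.transition_max_s <= self.window_s):
            raise ConfigError(
                "need transition_min_s < transition_max_s <= window_s, got "
                f"{self.transition_min_s}, {self.transition_max_s}, {self.window_s}"
            )
        for name in ("hold_min_s", "resample_hz", "bessel_fc_hz", "quality_window_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.bessel_order < 1:
            raise ConfigError("bessel_order must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def nyquist_hz(interval_s: float) -> float:
    """Nyquist frequency of sampling once every ``interval_s`` seconds.

    Manual CRT is rarely taken more often than every 15 min, i.e. a Nyquist
    frequency of ~0.55 mHz -- the rationale for the 2 mHz / 0.5 mHz smoothing
    cut-offs applied to the automated series.
    """
    if interval_s <= 0:
        raise ValueError("interval must be > 0")
    return 1.0 / (2.0 * interval_s)
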