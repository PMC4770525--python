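"""Conditioning of per-refill CRTs into smooth time series and quality
indices.

Accepted refill times are linearly interpolated and resampled onto a uniform
0.1 Hz grid, then low-pass filtered with a 2 mHz second-order forward-reverse
(zero-phase) Bessel filter; at 520 nm an additional 0.5 mHz stage is cascaded
by default.  The cut-offs reflect clinical practice: manual CRT is rarely
taken more often than every 15 min, a sampling interval whose Nyquist
frequency is ~0.55 mHz.

Quality indices: the percentage of used refills over a centred 10 min rolling
window, and the blanching modulation-depth series, both smoothed with the
same zero-phase filter.

Long dropouts are not interpolated across: gaps between consecutive used
refills longer than ``gap_max_s`` (default five cuff cycles) split the series
into blocks that are filtered independently; grid cells inside a gap carry
NaN.  Bridging long gaps by interpolation would fabricate data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .datamodel import PipelineConfig, nyquist_hz  # noqa: F401  (re-exported helper)
from .errors import InsufficientDataError

log = logging.getLogger(__name__)


def resample(times: np.ndarray, values: np.ndarray, rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation onto a uniform grid spanning [first, last] event.

    No extrapolation beyond the data.  Raises
    :class:`InsufficientDataError` for fewer than 2 points.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 2:
        raise InsufficientDataError(f"resample needs >= 2 points, got {len(times)}")
    if np.any(np.diff(times) <= 0):
        raise ValueError("event times must be strictly increasing")
    n = int(math.floor((times[-1] - times[0]) * rate_hz)) + 1
    grid = times[0] + np.arange(n) / rate_hz
    return grid, np.interp(grid, times, values)


def _bessel_sos(fc_hz: float, order: int, rate_hz: float):
    if not (0 < fc_hz < rate_hz / 2):
        raise ValueError(f"fc must be in (0, Nyquist={rate_hz / 2}), got {fc_hz}")
    # 'mag' normalisation puts the -3 dB point at fc; bilinear discretisation
    # maps s=0 to z=1 so DC gain stays exactly 1.
    return signal.bessel(order, fc_hz, btype="low", analog=False, norm="mag",
                         output="ba", fs=rate_hz)


def bessel_padlen(fc_hz: float, order: int, rate_hz: float) -> int:
    """Reflection-padding length: at least 3 filter time constants."""
    tau_samples = rate_hz / (2 * np.pi * fc_hz)
    return max(int(np.ceil(3 * tau_samples)), 3 * (order + 1))


def bessel_zero_phase(
    series: np.ndarray, fc_hz: float = 0.002, order: int = 2, rate_hz: float = 0.1
) -> np.ndarray:
    """Forward-reverse second-order Bessel low-pass (zero net phase).

    The effective magnitude response is the single-pass response squared, so
    a sinusoid at fc emerges at ~half amplitude; DC gain is exactly 1.  Edges
    are handled by odd reflection padding of >= 3 filter time constants;
    shorter series raise :class:`InsufficientDataError`.
    """
    series = np.asarray(series, dtype=float)
    b, a = _bessel_sos(fc_hz, order, rate_hz)
    padlen = bessel_padlen(fc_hz, order, rate_hz)
    if len(series) <= padlen:
        raise InsufficientDataError(
            f"series of {len(series)} samples shorter than required padding {padlen}"
        )
    return signal.filtfilt(b, a, series, padtype="odd", padlen=padlen)


def filter_blocks(
    series: np.ndarray, fc_hz: float, order: int, rate_hz: float
) -> np.ndarray:
    """Zero-phase filter each contiguous finite run; NaN gaps are preserved.

    Runs too short for the reflection padding are passed through unfiltered
    with a logged notice.
    """
    out = np.asarray(series, dtype=float).copy()
    finite = np.isfinite(out)
    if not finite.any():
        return out
    edges = np.diff(finite.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if finite[0]:
        starts.insert(0, 0)
    if finite[-1]:
        ends.append(len(out))
    for s, e in zip(starts, ends):
        try:
            out[s:e] = bessel_zero_phase(out[s:e], fc_hz, order, rate_hz)
        except InsufficientDataError:
            log.info("block of %d samples too short to filter; left raw", e - s)
    return out


def rolling_used_fraction(
    event_times: np.ndarray,
    used: np.ndarray,
    window_s: float,
    grid: np.ndarray,
) -> np.ndarray:
    """Percentage of used refills in a centred rolling window, on ``grid``.

    Windows containing no events yield NaN (carried as a gap).
    """
    event_times = np.asarray(event_times, dtype=float)
    used = np.asarray(used, dtype=bool)
    order = np.argsort(event_times)
    event_times = event_times[order]
    cum = np.concatenate(([0], np.cumsum(used[order])))
    lo = np.searchsorted(event_times, np.asarray(grid) - window_s / 2, side="left")
    hi = np.searchsorted(event_times, np.asarray(grid) + window_s / 2, side="right")
    total = hi - lo
    n_used = cum[hi] - cum[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * n_used / np.maximum(total, 1), np.nan)
    return pct


@dataclass
class CRTSeries:
    """Conditioned refill-time series for one wavelength."""

    wavelength: int
    times: np.ndarray                 # used-refill event times
    crt: np.ndarray                   # raw CRTs at those events
    resampled_times: np.ndarray = field(default_factory=lambda: np.array([]))
    resampled_crt: np.ndarray = field(default_factory=lambda: np.array([]))
    filtered_crt: np.ndarray = field(default_factory=lambda: np.array([]))
    used_fraction: np.ndarray = field(default_factory=lambda: np.array([]))
    modulation_depth_series: np.ndarray = field(default_factory=lambda: np.array([]))


def condition_series(refills: pd.DataFrame, cfg: PipelineConfig) -> dict[int, CRTSeries]:
    """Build a :class:`CRTSeries` per wavelength from a per-refill table
    (schema of :data:`crtpipe.refill.REFILL_COLUMNS`)."""
    out: dict[int, CRTSeries] = {}
    for w, grp in refills.groupby("wavelength_nm"):
        w = int(w)
        used = grp[grp["status"] == "used"].sort_values("release_time_s")
        times = used["release_time_s"].to_numpy(float)
        crt = used["crt_s"].to_numpy(float)
        series = CRTSeries(wavelength=w, times=times, crt=crt)
        if len(times) >= 2:
            grid, vals = resample(times, crt, cfg.resample_hz)
            # blank out grid cells spanned by over-long event gaps
            gaps = np.flatnonzero(np.diff(times) > cfg.gap_max_s)
            for g in gaps:
                vals[(grid > times[g]) & (grid < times[g + 1])] = np.nan
            filt = filter_blocks(vals, cfg.bessel_fc_hz, cfg.bessel_order, cfg.resample_hz)
            if w == 520 and cfg.cascade_520:
                filt = filter_blocks(filt, cfg.bessel_fc2_hz, cfg.bessel_order, cfg.resample_hz)
            series.resampled_times = grid
            series.resampled_crt = vals
            series.filtered_crt = filt
            ev_t = grp["release_time_s"].to_numpy(float)
            ev_used = (grp["status"] == "used").to_numpy()
            pct = rolling_used_fraction(ev_t, ev_used, cfg.quality_window_s, grid)
            series.used_fraction = filter_blocks(
                pct, cfg.bessel_fc_hz, cfg.bessel_order, cfg.resample_hz
            )
            md = used["modulation_depth"].to_numpy(float)
            ok = np.isfinite(md)
            if ok.sum() >= 2:
                md_on_grid = np.interp(grid, times[ok], md[ok])
                series.modulation_depth_series = filter_blocks(
                    md_on_grid, cfg.bessel_fc_hz, cfg.bessel_order, cfg.resample_hz
                )
        out[w] = series
    return out


def series_frame(series: dict[int, CRTSeries]) -> pd.DataFrame:
    """Flatten conditioned series to the ``t_s,wavelength_nm,crt_raw_s,
    crt_filt_s,used_pct,mod_depth`` CSV schema."""
    frames = []
    for w, s in sorted(series.items()):
        if len(s.resampled_times) == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "t_s": s.resampled_times,
                    "wavelength_nm": w,
                    "crt_raw_s": s.resampled_crt,
                    "crt_filt_s": s.filtered_crt,
                    "used_pct": s.used_fraction if len(s.used_fraction) else np.nan,
                    "mod_depth": s.modulation_depth_series
                    if len(s.modulation_depth_series)
                    else np.nan,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["t_s", "wavelength_nm", "crt_raw_s", "crt_filt_s", "used_pct", "mod_depth"]
        )
    return pd.concat(frames, ignore_index=True)
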