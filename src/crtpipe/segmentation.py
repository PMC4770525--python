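"""Pressure-release detection and refill-window extraction.

A *release* is the first sample where cuff pressure drops below the lower
hysteresis threshold (3.1 kPa) after having risen above the upper threshold
(3.5 kPa) and remained above it for at least the minimum hold time (1 s).
"remained above that level" is read against the upper threshold: the arming
run must stay above 3.5 kPa for the full hold.  Once armed, brief dips into
the 3.1-3.5 kPa band do not disarm; only a release fires (and resets) the
hysteresis state.

Each release yields one 10 s refill window per wavelength, starting at the
first sample at/after the release, with the spot temperature read at the
release sample.  Windows cut short by the end of the recording are flagged
``truncated`` and excluded from fitting.
"""

from __future__ import annotations

import logging

import numpy as np

from .datamodel import DeviceRecording, PipelineConfig, RefillSegment

log = logging.getLogger(__name__)


def release_indices(rec: DeviceRecording, cfg: PipelineConfig) -> np.ndarray:
    """Sample indices of detected releases, in increasing order."""
    p = rec.pressure
    t = rec.time
    n = len(p)
    if n == 0:
        return np.array([], dtype=int)
    above = p > cfg.pressure_upper_kpa
    below = p < cfg.pressure_lower_kpa

    # contiguous runs of `above`
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1)  # inclusive run end
    if above[0]:
        starts = np.insert(starts, 0, 0)
    if above[-1]:
        ends = np.append(ends, n - 1)

    # arming instant: first sample at which the run has spanned >= hold_min_s
    arm_idx = []
    eps = 1e-9
    for s, e in zip(starts, ends):
        if t[e] - t[s] + eps >= cfg.hold_min_s:
            j = int(np.searchsorted(t, t[s] + cfg.hold_min_s - eps))
            arm_idx.append(min(j, e))
    below_idx = np.flatnonzero(below)

    releases = []
    last = -1
    for a in arm_idx:
        if a <= last:
            continue  # armed state already pending/consumed for this stretch
        pos = int(np.searchsorted(below_idx, a))
        if pos >= len(below_idx):
            break
        b = int(below_idx[pos])
        releases.append(b)
        last = b
    return np.asarray(releases, dtype=int)


def detect_releases(rec: DeviceRecording, cfg: PipelineConfig) -> np.ndarray:
    """Release times (s).  An empty array is a valid result."""
    idx = release_indices(rec, cfg)
    return rec.time[idx] if len(idx) else np.array([], dtype=float)


def extract_segments(
    rec: DeviceRecording,
    releases: np.ndarray,
    cfg: PipelineConfig,
    wavelengths=None,
) -> list[RefillSegment]:
    """One :class:`RefillSegment` per (release x wavelength).

    Interior segments contain ``round(window_s * sample_rate) + 1`` samples;
    a release too close to the end of the recording yields a truncated
    segment (flagged, excluded from fitting downstream).  Releases beyond the
    recording end are skipped with a logged warning.
    """
    if wavelengths is None:
        wavelengths = sorted(rec.intensity)
    n_win = int(round(cfg.window_s * rec.sample_rate)) + 1
    segments: list[RefillSegment] = []
    for rt in np.atleast_1d(releases):
        i0 = int(np.searchsorted(rec.time, rt - 1e-9))
        if i0 >= len(rec):
            log.warning("release at %.3f s beyond recording end; skipped", rt)
            continue
        i1 = min(i0 + n_win, len(rec))
        truncated = (i1 - i0) < n_win
        spot = float(rec.temperature[i0])
        for w in wavelengths:
            segments.append(
                RefillSegment(
                    release_time_s=float(rt),
                    time_rel=rec.time[i0:i1] - rt,
                    intensity=rec.intensity[w][i0:i1],
                    wavelength=int(w),
                    spot_temperature_c=spot,
                    truncated=truncated,
                    sample_rate=rec.sample_rate,
                )
            )
    return segments
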