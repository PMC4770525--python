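"""Two-part refill fitting, rejection rules and threshold CRT extraction.

Each 10 s post-release window is modelled in two parts: a second-order
polynomial over region 1 (the capillary refill, ``[0, t*]``) and a straight
line over region 2 (the baseline, ``[t*, window]``).  The transition time
``t*`` is scanned over a 1-6 s grid (one optical sample period per step) and
the value minimising the pooled RMS residual of both fits is kept.

A refill is rejected when, checked in this order, (1) the pooled RMS error at
the optimum exceeds ``max_rms_error``, (2) the refill region is not
net-decreasing in intensity (mean slope of the quadratic over region 1
positive -- intensity must fall as blood returns), or (3) the baseline-line
slope magnitude exceeds ``max_baseline_slope`` (too much drift).  A fourth,
``no_crossing``, covers accepted fits whose raw trace never reaches the
threshold level.

CRT is the time after release at which the *raw* intensity first falls to
``baseline + level * initial_height``, where the baseline is the region-2
line extrapolated to the release instant and ``initial_height`` is the first
window sample above that baseline; the crossing is located by linear
interpolation between the bracketing samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datamodel import DeviceRecording, PipelineConfig, RefillSegment
from .errors import InsufficientDataError
from .segmentation import extract_segments, release_indices

log = logging.getLogger(__name__)

REJECT_REASONS = ("none", "rms_error", "refill_slope", "baseline_drift", "truncated", "no_crossing")


@dataclass
class RefillFitResult:
    """Per-segment two-part fit outcome."""

    release_time_s: float
    wavelength: int
    transition_s: float = math.nan
    poly_coeffs: tuple = ()          # (a2, a1, a0), highest power first
    line_coeffs: tuple = ()          # (slope, intercept)
    rms_error: float = math.nan      # pooled over both regions at optimum
    region1_mean_slope: float = math.nan
    baseline_slope: float = math.nan
    baseline_at_release: float = math.nan
    initial_height: float = math.nan
    status: str = "rejected"
    reject_reason: str = "truncated"
    crt_s: float | None = None
    spot_temperature_c: float = math.nan

    @property
    def used(self) -> bool:
        return self.status == "used"


def _scan_transitions(x: np.ndarray, y: np.ndarray, cfg: PipelineConfig):
    """Vectorised transition scan.

    Returns (best index into x, pooled rms at every candidate, candidate
    indices).  Candidate transitions are the samples whose time lies in
    [transition_min_s, transition_max_s] with >=3 samples in region 1 and
    >=2 in region 2.
    """
    n = len(x)
    cand = np.flatnonzero(
        (x >= cfg.transition_min_s - 1e-12)
        & (x <= cfg.transition_max_s + 1e-12)
        & (np.arange(n) >= 2)
        & (np.arange(n) <= n - 2)
    )
    if len(cand) == 0:
        raise InsufficientDataError("no valid transition candidates in segment")

    # prefix/suffix power sums for the normal equations
    pows = [np.ones_like(x), x, x * x, x**3, x**4]
    cp = [np.cumsum(p) for p in pows]          # prefix sums of t^k
    cpy = [np.cumsum(p * y) for p in pows[:3]]  # prefix sums of t^k * y
    sp = [np.cumsum(p[::-1])[::-1] for p in pows[:3]]   # suffix sums t^k
    spy = [np.cumsum((p * y)[::-1])[::-1] for p in pows[:2]]

    m = len(cand)
    A1 = np.empty((m, 3, 3))
    b1 = np.empty((m, 3))
    for r in range(3):
        for c in range(3):
            A1[:, r, c] = cp[r + c][cand]
        b1[:, r] = cpy[r][cand]
    A2 = np.empty((m, 2, 2))
    b2 = np.empty((m, 2))
    for r in range(2):
        for c in range(2):
            A2[:, r, c] = sp[r + c][cand]
        b2[:, r] = spy[r][cand]
    coef1 = np.linalg.solve(A1, b1[..., None])[..., 0]  # (m,3): c0 + c1 t + c2 t^2
    coef2 = np.linalg.solve(A2, b2[..., None])[..., 0]  # (m,2): d0 + d1 t

    # pooled residuals, evaluated directly (broadcast) for numerical accuracy
    pred1 = coef1[:, 0:1] + coef1[:, 1:2] * x + coef1[:, 2:3] * (x * x)
    pred2 = coef2[:, 0:1] + coef2[:, 1:2] * x
    idx = np.arange(n)
    mask1 = idx <= cand[:, None]
    mask2 = idx >= cand[:, None]
    r1 = np.where(mask1, y - pred1, 0.0)
    r2 = np.where(mask2, y - pred2, 0.0)
    counts = (cand + 1) + (n - cand)
    rms = np.sqrt((np.sum(r1 * r1, axis=1) + np.sum(r2 * r2, axis=1)) / counts)
    best = int(cand[int(np.argmin(rms))])
    return best, rms, cand


def fit_refill(seg: RefillSegment, cfg: PipelineConfig) -> RefillFitResult:
    """Fit the two-part model; classification is left to
    :func:`classify_refill`.

    Truncated or too-short segments come back pre-rejected with reason
    ``truncated``.
    """
    res = RefillFitResult(
        release_time_s=seg.release_time_s,
        wavelength=seg.wavelength,
        spot_temperature_c=seg.spot_temperature_c,
    )
    if seg.truncated or len(seg.time_rel) < 5:
        return res
    x, y = seg.time_rel, seg.intensity
    try:
        best, _, _ = _scan_transitions(x, y, cfg)
    except InsufficientDataError:
        return res

    # refit at the optimum for clean coefficients and an exact residual norm
    p1 = np.polyfit(x[: best + 1], y[: best + 1], 2)
    p2 = np.polyfit(x[best:], y[best:], 1)
    r1 = y[: best + 1] - np.polyval(p1, x[: best + 1])
    r2 = y[best:] - np.polyval(p2, x[best:])
    rms = float(np.sqrt((r1 @ r1 + r2 @ r2) / (len(r1) + len(r2))))

    t_star = float(x[best])
    if cfg.refill_slope_from_line:
        l1 = np.polyfit(x[: best + 1], y[: best + 1], 1)
        slope1 = float(l1[0])
    else:
        # mean slope of the quadratic over region 1 = slope of its secant
        slope1 = float(
            (np.polyval(p1, t_star) - np.polyval(p1, x[0])) / (t_star - x[0])
        )
    baseline0 = float(np.polyval(p2, 0.0))
    return replace(
        res,
        transition_s=t_star,
        poly_coeffs=tuple(p1),
        line_coeffs=tuple(p2),
        rms_error=rms,
        region1_mean_slope=slope1,
        baseline_slope=float(p2[0]),
        baseline_at_release=baseline0,
        initial_height=float(y[0] - baseline0),
        status="pending",
        reject_reason="none",
    )


def classify_refill(fit: RefillFitResult, cfg: PipelineConfig) -> RefillFitResult:
    """Apply the rejection rules in order; first hit wins."""
    if fit.reject_reason == "truncated":
        return fit
    if fit.rms_error > cfg.max_rms_error:
        return replace(fit, status="rejected", reject_reason="rms_error")
    # strict positivity up to float round-off (a flat region-1 fit carries
    # slope noise of order 1e-13 counts/s)
    if fit.region1_mean_slope > 1e-9:
        return replace(fit, status="rejected", reject_reason="refill_slope")
    if abs(fit.baseline_slope) > cfg.max_baseline_slope:
        return replace(fit, status="rejected", reject_reason="baseline_drift")
    return replace(fit, status="used", reject_reason="none")


def crt_from_threshold(
    seg: RefillSegment, fit: RefillFitResult, level: float | None = None
) -> float | None:
    """Fractional-threshold CRT from the raw trace, or None if no crossing.

    For a fixed monotone decay this is monotonically decreasing in ``level``.
    """
    if level is None:
        level = 0.20
    if not (0.0 < level < 1.0):
        raise ValueError("threshold level must be in (0,1)")
    if fit.initial_height <= 0:
        return None
    target = fit.baseline_at_release + level * fit.initial_height
    y = seg.intensity
    x = seg.time_rel
    under = np.flatnonzero(y < target)
    under = under[under > 0]
    if len(under) == 0:
        return None
    i = int(under[0])
    y0, y1 = y[i - 1], y[i]
    frac = (y0 - target) / (y0 - y1) if y0 != y1 else 0.0
    return float(x[i - 1] + frac * (x[i] - x[i - 1]))


def analyze_segment(seg: RefillSegment, cfg: PipelineConfig) -> RefillFitResult:
    """fit -> classify -> threshold CRT for one segment."""
    fit = classify_refill(fit_refill(seg, cfg), cfg)
    if not fit.used:
        return fit
    crt = crt_from_threshold(seg, fit, cfg.threshold_level)
    if crt is None:
        return replace(fit, status="rejected", reject_reason="no_crossing", crt_s=None)
    return replace(fit, crt_s=crt)


def modulation_depth(
    rec: DeviceRecording,
    release_time_s: float,
    cfg: PipelineConfig,
    wavelength: int = 520,
) -> float:
    """Fractional intensity rise above baseline at peak blanching.

    Baseline is the mean intensity over the 2 s immediately before inflation
    onset; the peak is taken between onset and the release.  Returns NaN
    (with a logged warning) when the baseline is undefined or non-positive.
    """
    i_rel = int(np.searchsorted(rec.time, release_time_s - 1e-9))
    p = rec.pressure
    j = i_rel - 1
    while j >= 0 and p[j] >= cfg.pressure_lower_kpa:
        j -= 1
    onset = j + 1
    if onset >= i_rel or np.max(p[onset : i_rel + 1]) <= cfg.pressure_upper_kpa:
        log.warning("no pressure application found before release at %.1f s", release_time_s)
        return math.nan
    t_on = rec.time[onset]
    base_mask = (rec.time >= t_on - 2.0) & (rec.time < t_on)
    if not np.any(base_mask):
        log.warning("no pre-inflation baseline window before %.1f s", release_time_s)
        return math.nan
    baseline = float(np.nanmean(rec.intensity[wavelength][base_mask]))
    if not (baseline > 0):
        log.warning("non-positive baseline before release at %.1f s", release_time_s)
        return math.nan
    peak = float(np.nanmax(rec.intensity[wavelength][onset : i_rel + 1]))
    return (peak - baseline) / baseline


REFILL_COLUMNS = [
    "release_time_s",
    "wavelength_nm",
    "status",
    "reject_reason",
    "transition_s",
    "rms_error",
    "crt_s",
    "modulation_depth",
    "spot_temp_c",
]


def analyze_recording(
    rec: DeviceRecording, cfg: PipelineConfig, wavelengths=None
) -> pd.DataFrame:
    """Full per-refill analysis of a recording.

    Returns one row per (release x wavelength) with fit status, CRT and the
    520 nm blanching modulation depth attached to every wavelength row of the
    same release.
    """
    idx = release_indices(rec, cfg)
    releases = rec.time[idx] if len(idx) else np.array([])
    segments = extract_segments(rec, releases, cfg, wavelengths=wavelengths)
    depth_by_release = {
        float(rt): modulation_depth(rec, float(rt), cfg) for rt in releases
    }
    rows = []
    for seg in segments:
        fit = analyze_segment(seg, cfg)
        rows.append(
            {
                "release_time_s": fit.release_time_s,
                "wavelength_nm": fit.wavelength,
                "status": fit.status,
                "reject_reason": fit.reject_reason,
                "transition_s": fit.transition_s,
                "rms_error": fit.rms_error,
                "crt_s": fit.crt_s,
                "modulation_depth": depth_by_release.get(fit.release_time_s, math.nan),
                "spot_temp_c": fit.spot_temperature_c,
            }
        )
    return pd.DataFrame(rows, columns=REFILL_COLUMNS)
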