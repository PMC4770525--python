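"""Synthetic CRT device recordings with known ground truth.

The simulator emulates what the datalogger records during an automated
capillary-refill session: every ``cycle_period_s`` (default 23 s) the cuff
inflates to ~17 kPa, holds for 7 s to blanch the capillary bed, then vents
through the solenoid valve (exponential decay down to a small residual
pressure).  Blanching raises diffuse reflectance -- by about 60% at 520 nm,
much less at 640/950 nm -- and after the release the intensity decays back to
baseline as the capillaries refill.

The refill decay is ``I(t) = B(t) + A * g((t - t_release)/tau)`` with ``g``
a monotone decay, ``g(0) = 1``.  ``tau`` is chosen so that the fractional
threshold definition of CRT recovers the requested ground-truth time
analytically: for the default exponential shape the CRT at threshold level
``L`` is ``tau * ln(1/L)``; for the quadratic-plateau option
``g(x) = (1 - x/2)^2`` (zero beyond x=2) it is ``2 * tau * (1 - sqrt(L))``.
The decay starts at the exact instant the simulated pressure crosses the
release threshold -- the same event the segmenter detects -- so extracted and
true CRTs share a time origin to within one sample.

Ambient temperature modulates the true CRT multiplicatively:
``crt(T) = crt_ref * (1 + s * (T - T_ref))`` with sensitivity ``s`` in
fractional change per degC (cooling lengthens the refill; published manual
CRT studies report roughly -5%/degC warming, so the default is negative).

Confounds available: linear baseline drift, cardiac-synchronous sinusoidal
ripple (most visible at 520 nm), white measurement noise, and randomly timed
motion artifacts (step / spike / baseline tilt).  All randomness flows from a
single integer seed; ground truth is emitted alongside the recording, never
re-derived from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import WAVELENGTHS, DeviceRecording
from .errors import ParameterError

TRUTH_COLUMNS = ["release_time_s", "wavelength_nm", "true_crt_s", "tau_s", "artifact_flag"]

_ARTIFACT_KINDS = ("step", "spike", "tilt")
_SPIKE_SD_S = 0.15
_TILT_RAMP_S = 5.0


def _per_wavelength(value, name: str) -> dict[int, float]:
    if isinstance(value, Mapping):
        out = {int(w): float(value[w]) for w in value}
        missing = set(WAVELENGTHS) - set(out)
        if missing:
            raise ParameterError(f"{name} missing wavelengths {sorted(missing)}")
        return out
    return {w: float(value) for w in WAVELENGTHS}


@dataclass
class SimulationParams:
    """Study conditions for a simulated session.

    Defaults reproduce the device's published operating point: 23 s cycle, 7 s
    hold at 17 kPa, ~60% blanching modulation at 520 nm, 62.04 Hz optical
    sample rate, ~1.3 s resting CRT (defined at the 20% threshold level).
    """

    session_length_s: float = 23.0 * 20
    cycle_period_s: float = 23.0
    hold_s: float = 7.0
    ramp_s: float = 1.0
    apply_pressure_kpa: float = 17.0
    vent_tau_s: float = 0.15
    residual_kpa: float = 0.2
    release_threshold_kpa: float = 3.1   # pressure at which refill starts
    sample_rate_hz: float = 62.04
    true_crt_s: float | Mapping[int, float] = 1.3
    crt_reference_level: float = 0.20    # threshold level defining true_crt_s
    refill_shape: str = "quadratic"      # or "exponential"
    blanch_gain: float | Mapping[int, float] = field(
        default_factory=lambda: {520: 0.60, 640: 0.15, 950: 0.20}
    )
    baseline_counts: float | Mapping[int, float] = 1000.0
    drift_counts_per_s: float = 0.0
    cardiac_amplitude_counts: float | Mapping[int, float] = field(
        default_factory=lambda: {520: 5.0, 640: 1.0, 950: 1.0}
    )
    cardiac_rate_hz: float = 1.2
    noise_sd_counts: float = 10.0
    artifact_rate_per_hour: float = 0.0
    artifact_amplitude_counts: float = 50.0
    temperature_profile: tuple[Sequence[float], Sequence[float]] = ((0.0,), (33.0,))
    temp_noise_sd_c: float = 0.01
    temp_sensitivity_per_c: float = -0.07
    reference_temp_c: float = 33.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycle_period_s <= self.hold_s:
            raise ParameterError(
                f"cycle_period_s ({self.cycle_period_s}) must exceed hold_s ({self.hold_s})"
            )
        if self.cycle_period_s <= self.ramp_s + self.hold_s:
            raise ParameterError("cycle too short for ramp + hold + vent")
        if self.refill_shape not in ("exponential", "quadratic"):
            raise ParameterError(f"unknown refill_shape {self.refill_shape!r}")
        if not (0.0 < self.crt_reference_level < 1.0):
            raise ParameterError("crt_reference_level must be in (0,1)")
        self.true_crt_s = _per_wavelength(self.true_crt_s, "true_crt_s")
        for w, c in self.true_crt_s.items():
            if not (0.0 < c < 10.0):
                raise ParameterError(f"true_crt_s[{w}] must be in (0,10), got {c}")
        self.blanch_gain = _per_wavelength(self.blanch_gain, "blanch_gain")
        self.baseline_counts = _per_wavelength(self.baseline_counts, "baseline_counts")
        self.cardiac_amplitude_counts = _per_wavelength(
            self.cardiac_amplitude_counts, "cardiac_amplitude_counts"
        )
        for name in ("noise_sd_counts", "artifact_rate_per_hour", "artifact_amplitude_counts"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not (self.residual_kpa < self.release_threshold_kpa < self.apply_pressure_kpa):
            raise ParameterError("need residual < release_threshold < apply pressure")


def _crt_to_tau(crt: float, level: float, shape: str) -> float:
    if shape == "exponential":
        return crt / math.log(1.0 / level)
    return crt / (2.0 * (1.0 - math.sqrt(level)))  # quadratic plateau


def _decay(x: np.ndarray, shape: str) -> np.ndarray:
    if shape == "exponential":
        return np.exp(-np.clip(x, 0.0, 700.0))
    g = np.clip(1.0 - x / 2.0, 0.0, None)
    return g * g


def simulate_session(params: SimulationParams) -> tuple[DeviceRecording, pd.DataFrame]:
    """Generate one session; returns the recording and its ground truth.

    The ground-truth table has one row per (release x wavelength):
    ``release_time_s`` (exact analytic release instant), ``true_crt_s`` (CRT
    at the reference threshold level after temperature modulation), ``tau_s``
    and ``artifact_flag`` (True when an injected artifact lands inside the
    10 s window after that release).
    """
    p = params
    rng = np.random.default_rng(p.seed)
    fs = p.sample_rate_hz
    n = int(round(p.session_length_s * fs))
    t = np.arange(n) / fs
    n_cycles = int(math.floor(p.session_length_s / p.cycle_period_s))

    # ---- pressure waveform -------------------------------------------
    pressure = np.full(n, p.residual_kpa)
    span = p.apply_pressure_kpa - p.residual_kpa
    vent_start_ph = p.ramp_s + p.hold_s
    # phase (s within cycle) at which pressure crosses the release threshold
    rel_phase = vent_start_ph + p.vent_tau_s * math.log(
        span / (p.release_threshold_kpa - p.residual_kpa)
    )
    up_phase = p.ramp_s * (p.release_threshold_kpa - p.residual_kpa) / span
    cyc = np.floor(t / p.cycle_period_s).astype(int)
    phase = t - cyc * p.cycle_period_s
    active = cyc < n_cycles
    ramp_m = active & (phase < p.ramp_s)
    hold_m = active & (phase >= p.ramp_s) & (phase < vent_start_ph)
    vent_m = active & (phase >= vent_start_ph)
    pressure[ramp_m] = p.residual_kpa + span * phase[ramp_m] / p.ramp_s
    pressure[hold_m] = p.apply_pressure_kpa
    pressure[vent_m] = p.residual_kpa + span * np.exp(
        -(phase[vent_m] - vent_start_ph) / p.vent_tau_s
    )

    # ---- temperature --------------------------------------------------
    prof_t, prof_v = (np.asarray(a, dtype=float) for a in p.temperature_profile)
    temp_clean = np.interp(t, prof_t, prof_v)
    temperature = temp_clean + rng.normal(0.0, p.temp_noise_sd_c, n)

    # ---- per-release ground truth -------------------------------------
    release_times = np.arange(n_cycles) * p.cycle_period_s + rel_phase
    temp_at_release = np.interp(release_times, prof_t, prof_v)
    truth_rows = []
    taus = {}  # (cycle, wavelength) -> tau
    for w in WAVELENGTHS:
        scale = 1.0 + p.temp_sensitivity_per_c * (temp_at_release - p.reference_temp_c)
        crt_w = np.maximum(p.true_crt_s[w] * scale, 0.05)
        for k in range(n_cycles):
            tau = _crt_to_tau(float(crt_w[k]), p.crt_reference_level, p.refill_shape)
            taus[(k, w)] = tau
            truth_rows.append((release_times[k], w, float(crt_w[k]), tau, False))

    # ---- optical channels ---------------------------------------------
    intensity: dict[int, np.ndarray] = {}
    for w in WAVELENGTHS:
        base = p.baseline_counts[w] + p.drift_counts_per_s * t
        amp = p.blanch_gain[w] * p.baseline_counts[w]
        env = np.zeros(n)
        for k in range(n_cycles):
            t0 = k * p.cycle_period_s
            i0 = int(np.searchsorted(t, t0 + up_phase))
            i1 = int(np.searchsorted(t, t0 + p.ramp_s))
            i2 = int(np.searchsorted(t, t0 + rel_phase))
            i3 = int(np.searchsorted(t, t0 + p.cycle_period_s + up_phase)) if k + 1 < n_cycles else n
            env[i0:i1] = (t[i0:i1] - (t0 + up_phase)) / (p.ramp_s - up_phase)
            env[i1:i2] = 1.0
            env[i2:i3] = _decay((t[i2:i3] - (t0 + rel_phase)) / taus[(k, w)], p.refill_shape)
        sig = base + amp * env
        card = p.cardiac_amplitude_counts[w]
        if card > 0:
            sig = sig + card * np.sin(2 * np.pi * p.cardiac_rate_hz * t + rng.uniform(0, 2 * np.pi))
        if p.noise_sd_counts > 0:
            sig = sig + rng.normal(0.0, p.noise_sd_counts, n)
        intensity[w] = np.maximum(sig, 0.0)

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)

    rec = DeviceRecording(
        time=t,
        pressure=pressure,
        intensity=intensity,
        temperature=temperature,
        sample_rate=fs,
        meta={"seed": str(p.seed), "simulator": "crtpipe", "session_length_s": str(p.session_length_s)},
    )

    # ---- artifacts -----------------------------------------------------
    if p.artifact_rate_per_hour > 0:
        n_art = rng.poisson(p.artifact_rate_per_hour * p.session_length_s / 3600.0)
        for _ in range(n_art):
            at = float(rng.uniform(0.0, p.session_length_s))
            kind = str(rng.choice(_ARTIFACT_KINDS))
            ampl = float(p.artifact_amplitude_counts * rng.uniform(0.8, 1.5))
            rec = inject_artifact(rec, at, kind, ampl)
            dur = {"step": 0.0, "spike": 4 * _SPIKE_SD_S, "tilt": _TILT_RAMP_S}[kind]
            hit = (release_times <= at + dur) & (at <= release_times + 10.0)
            truth.loc[truth["release_time_s"].isin(release_times[hit]), "artifact_flag"] = True

    return rec, truth


def inject_artifact(
    rec: DeviceRecording, time_s: float, kind: str, amplitude: float
) -> DeviceRecording:
    """Return a copy of ``rec`` with a motion-like transient on all optical
    channels.

    Kinds: ``step`` (persistent offset from ``time_s`` on), ``spike``
    (Gaussian pulse, sd 0.15 s) and ``tilt`` (linear ramp over 5 s that then
    persists -- a baseline shift with finite slope).
    """
    if kind not in _ARTIFACT_KINDS:
        raise ParameterError(f"unknown artifact kind {kind!r}; choose from {_ARTIFACT_KINDS}")
    if not (rec.time[0] <= time_s <= rec.time[-1]):
        raise ParameterError(f"artifact time {time_s} outside recording")
    out = rec.copy()
    t = out.time
    if kind == "step":
        delta = amplitude * (t >= time_s)
    elif kind == "spike":
        delta = amplitude * np.exp(-0.5 * ((t - time_s) / _SPIKE_SD_S) ** 2)
    else:  # tilt
        delta = amplitude * np.clip((t - time_s) / _TILT_RAMP_S, 0.0, 1.0)
    for w in out.intensity:
        out.intensity[w] = np.maximum(out.intensity[w] + delta, 0.0)
    return out
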