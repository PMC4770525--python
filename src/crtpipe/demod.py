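"""Frequency-division multiplexed optical carriers and their DFT demodulator.

The device drives its three LED wavelengths with three sinusoidal carriers
spaced ~62 Hz apart around an 11.67 kHz centre, all sensed by one photodiode.
A complex local oscillator at the centre frequency downconverts the ADC
stream to baseband, and a rectangular non-overlapping DFT over one
carrier-spacing period (~16.1 ms) separates the channels: each carrier lands
exactly on a DFT bin (-1, 0, +1 relative to the centre), so with integer
cycles per window the channels are perfectly orthogonal and the demodulated
amplitude stream emerges at the carrier-spacing rate.

The scheme is parameterised in integer bin units so the orthogonality
invariant holds by construction: ``spacing = adc_rate / window_len`` and
``centre = centre_bin * spacing``.  The defaults (adc 46680 Hz, window 752
samples, centre bin 188) give a centre of exactly 11670 Hz and a spacing of
62.074 Hz.  :func:`CarrierScheme.from_frequencies` validates arbitrary
centre/spacing/rate triples and rejects any that do not give integer cycles
per window.

The front-end noise model summarises photocurrent shot noise, trans-impedance
thermal noise and op-amp voltage noise as an effective number of bits (ENOB)
as a function of the output bandwidth ``df``::

    ENOB(df) = 18.9 - 0.72 * ln(df)

e.g. 17.2 bits at a 10 Hz bandwidth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CarrierScheme:
    """Three-carrier frequency-division scheme in integer DFT-bin units."""

    adc_rate_hz: float = 46680.0
    window_len_samples: int = 752
    centre_bin: int = 188
    n_channels: int = 3

    def __post_init__(self) -> None:
        if self.window_len_samples < 8 or self.adc_rate_hz <= 0:
            raise ConfigError("degenerate carrier scheme")
        if self.n_channels != 3:
            raise ConfigError("scheme is defined for 3 channels")
        if not (1 < self.centre_bin < self.window_len_samples // 2 - 1):
            raise ConfigError("centre_bin must leave room for side carriers below Nyquist")

    @property
    def spacing_hz(self) -> float:
        return self.adc_rate_hz / self.window_len_samples

    @property
    def centre_hz(self) -> float:
        return self.centre_bin * self.spacing_hz

    @property
    def carrier_bins(self) -> tuple[int, int, int]:
        return (self.centre_bin - 1, self.centre_bin, self.centre_bin + 1)

    @property
    def carrier_freqs_hz(self) -> tuple[float, float, float]:
        return tuple(b * self.spacing_hz for b in self.carrier_bins)

    @classmethod
    def from_frequencies(
        cls, centre_hz: float, spacing_hz: float, adc_rate_hz: float, rtol: float = 1e-9
    ) -> "CarrierScheme":
        """Build a scheme from physical frequencies, requiring integer cycles
        per DFT window for every carrier (else :class:`ConfigError`)."""
        win = adc_rate_hz / spacing_hz
        if abs(win - round(win)) > rtol * win:
            raise ConfigError(
                f"adc_rate/spacing = {win} is not an integer: carriers would not "
                "complete integer cycles per window"
            )
        cbin = centre_hz / spacing_hz
        if abs(cbin - round(cbin)) > rtol * max(cbin, 1.0):
            raise ConfigError(
                f"centre/spacing = {cbin} is not an integer: centre carrier off-bin"
            )
        return cls(
            adc_rate_hz=adc_rate_hz,
            window_len_samples=int(round(win)),
            centre_bin=int(round(cbin)),
        )


def dft_bin_s(spacing_hz: float) -> float:
    """Length of one demodulator DFT bin in seconds (1/spacing, ~16.1 ms)."""
    if spacing_hz <= 0:
        raise ValueError("spacing must be > 0")
    return 1.0 / spacing_hz


def generate_drive(
    scheme: CarrierScheme,
    amplitudes,
    n_windows: int,
    phases=None,
    waveform: str = "sine",
) -> np.ndarray:
    """Synthesise the summed three-carrier photodiode waveform in ADC domain.

    ``amplitudes`` are per-channel carrier amplitudes (low, centre, high).
    With ``waveform="square"`` each carrier is a square wave of the given
    peak amplitude; its recoverable fundamental is ``4/pi`` times that.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.shape != (scheme.n_channels,):
        raise ValueError(f"need {scheme.n_channels} amplitudes, got {amplitudes.shape}")
    if phases is None:
        phases = np.zeros(scheme.n_channels)
    phases = np.asarray(phases, dtype=float)
    n = scheme.window_len_samples * int(n_windows)
    t = np.arange(n) / scheme.adc_rate_hz
    out = np.zeros(n)
    for a, f, ph in zip(amplitudes, scheme.carrier_freqs_hz, phases):
        carrier = np.sin(2 * np.pi * f * t + ph)
        if waveform == "square":
            carrier = np.sign(carrier)
        elif waveform != "sine":
            raise ValueError(f"unknown waveform {waveform!r}")
        out += a * carrier
    return out


def demodulate(waveform: np.ndarray, scheme: CarrierScheme) -> np.ndarray:
    """Recover per-channel carrier amplitudes, one row per DFT window.

    Multiplies by a complex local oscillator at the centre frequency, windows
    into non-overlapping blocks of one spacing period, DFTs each block and
    reports the magnitudes at relative bins (-1, 0, +1).  Output sample rate
    equals the carrier spacing.  A trailing partial window is dropped with a
    logged warning.

    Returns an array of shape ``(n_windows, 3)``.
    """
    waveform = np.asarray(waveform, dtype=float)
    nwin = scheme.window_len_samples
    n_windows, rem = divmod(len(waveform), nwin)
    if rem:
        log.warning("dropping trailing partial window of %d samples", rem)
        waveform = waveform[: n_windows * nwin]
    if n_windows == 0:
        return np.zeros((0, scheme.n_channels))
    blocks = waveform.reshape(n_windows, nwin)
    k = np.arange(nwin)
    # combined LO + DFT kernel: exp(-2j*pi*(centre_bin + offset)*k/N)
    kernels = np.stack(
        [np.exp(-2j * np.pi * b * k / nwin) for b in scheme.carrier_bins], axis=1
    )
    spectra = blocks @ kernels  # (n_windows, 3) complex
    return 2.0 * np.abs(spectra) / nwin


def enob(delta_f_hz: float) -> float:
    """Effective number of bits of the analog front end at output bandwidth
    ``delta_f_hz``: ``18.9 - 0.72 * ln(df)``.  Strictly decreasing in df."""
    delta_f_hz = float(delta_f_hz)
    if delta_f_hz <= 0:
        raise ValueError(f"bandwidth must be > 0, got {delta_f_hz}")
    return 18.9 - 0.72 * math.log(delta_f_hz)


def rms_sine(peak_to_peak: float) -> float:
    """RMS of a sinusoid given its peak-to-peak amplitude: pp / (2*sqrt(2)).

    A ~500 nA peak-to-peak photocurrent corresponds to ~177 nA RMS.
    """
    if peak_to_peak < 0:
        raise ValueError("peak-to-peak amplitude must be >= 0")
    return peak_to_peak / (2.0 * math.sqrt(2.0))


def selftest(seed: int = 0) -> dict:
    """Run the orthogonality/leakage checks and return pass/fail metrics."""
    rng = np.random.default_rng(seed)
    scheme = CarrierScheme()
    report: dict = {"scheme": {
        "adc_rate_hz": scheme.adc_rate_hz,
        "spacing_hz": scheme.spacing_hz,
        "centre_hz": scheme.centre_hz,
    }}
    # single-carrier leakage
    leak = 0.0
    for ch in range(3):
        amps = np.zeros(3)
        amps[ch] = 1.0
        out = demodulate(generate_drive(scheme, amps, 4), scheme)
        others = [c for c in range(3) if c != ch]
        leak = max(leak, float(np.max(out[:, others])))
    report["max_cross_leakage"] = leak
    # linear amplitude recovery on random triples
    err = 0.0
    for _ in range(5):
        amps = rng.uniform(0.1, 1.0, 3)
        out = demodulate(generate_drive(scheme, amps, 2), scheme)
        err = max(err, float(np.max(np.abs(out - amps) / amps)))
    report["max_recovery_rel_error"] = err
    report["passed"] = bool(leak < 1e-9 and err < 1e-9)
    return report
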