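# crtpipe

Signal-processing pipeline for **automated capillary refill time (CRT)**
measurement from a pneumatic-cuff, multi-wavelength reflectance sensor.

Capillary refill time — the time skin reflectance takes to return to baseline
after applied pressure blanches the capillary bed — is a simple bedside proxy
for peripheral perfusion, but manual assessment is poorly standardised
(pressure, duration, lighting, observer timing). An automated device applies
~17 kPa (130 mmHg) by cuff for 7 s, releases it, and records diffuse
reflectance at 520/640/950 nm plus cuff pressure and skin-surface
temperature, repeating every 23 s. This package implements the analysis that
turns those recordings into CRT series and validation statistics, together
with a simulator that generates such recordings with known ground truth.

For physiological-monitoring researchers and medical-device engineers who
want a tested, reproducible reference implementation of the full chain.

## What it computes

1. **Demodulation model** (`crtpipe.demod`) — the sensor drives its LEDs with
   three frequency-division-multiplexed carriers (~62 Hz spacing around an
   11.67 kHz centre); a complex local oscillator plus a rectangular DFT over
   one spacing period (~16.1 ms) separates the channels with exact
   orthogonality. The front-end noise model is summarised as an effective
   number of bits, `ENOB(Δf) = 18.9 − 0.72 ln Δf` (17.2 bits at Δf = 10 Hz).
2. **Segmentation** (`crtpipe.segmentation`) — a release is the first sample
   with cuff pressure < 3.1 kPa after ≥ 1 s above 3.5 kPa; each release opens
   a 10 s refill window per wavelength.
3. **Two-part refill fit** (`crtpipe.refill`) — each window is fitted as a
   quadratic (refill, `[0, t*]`) plus a straight line (baseline,
   `[t*, 10 s]`); the transition `t*` is scanned over 1–6 s and the pooled
   RMS-minimising value kept. Refills with excessive RMS error, a
   non-decreasing refill region, or excessive baseline drift are rejected.
   CRT is the interpolated time at which raw intensity first falls to
   `baseline + L·(initial height)`, with threshold level `L` (default 0.20).
4. **Conditioning** (`crtpipe.postprocess`) — accepted CRTs are resampled at
   0.1 Hz and smoothed with a 2 mHz second-order forward–reverse (zero-phase)
   Bessel filter (0.5 mHz cascaded at 520 nm), with a rolling used-refill
   percentage and blanching modulation-depth quality indices.
5. **Validation statistics** (`crtpipe.stats`) — Pearson r between inverse
   CRT and spot temperature with Fisher-z′ 95% confidence intervals
   (`z′ = atanh r`, SE `1/√(n−3)`), per-cohort significance counts, and
   0.1 s × 0.25 °C binned densities with best-fit lines.
6. **Simulator** (`crtpipe.simulate`) — generates full sessions with
   controllable ground-truth CRT, temperature sensitivity, drift, cardiac
   ripple, noise and motion artifacts.

## Worked example

Simulate a subject cooled from 33 °C to 25 °C over ~46 minutes (CRT
sensitivity −5 %/°C) and recover the temperature relationship:

```python
from crtpipe import PipelineConfig, analyze_recording
from crtpipe.simulate import SimulationParams, simulate_session
from crtpipe.stats import (binned_density, inverse_crt_pairs,
                           pearson_fisher, percent_per_degree)

length = 23.0 * 120                       # one refill every 23 s
params = SimulationParams(
    session_length_s=length, seed=42,
    temp_sensitivity_per_c=-0.05,
    temperature_profile=((0.0, length), (33.0, 25.0)),
)
rec, truth = simulate_session(params)
refills = analyze_recording(rec, PipelineConfig(), wavelengths=[520])
temp, inv = inverse_crt_pairs(refills)
res = pearson_fisher(temp, inv)
d = binned_density(refills)
```

This prints (via the survey statements in the repository's example):

```
refills analysed: 120, used: 120 (100.0%)
mean CRT: 1.52 s, mean modulation depth: 0.63
inverse CRT vs temperature: r = 0.959, 95% CI = (0.942, 0.971), n = 120, significant: True
fit slope: -0.064 s/degC -> 4.9% CRT change per degC
```

All 120 refills pass the rejection rules; the mean CRT of 1.52 s reflects the
1.3 s reference CRT lengthened by cooling; the blanching raises 520 nm
intensity by ~60% (the 0.63 modulation depth); inverse CRT correlates
positively and significantly with temperature; and the fitted slope recovers
the simulated −5 %/°C sensitivity.

The same chain is available from the shell:

```sh
crtpipe simulate --seed 42 --length 2760 --out rec.csv --truth truth.csv
crtpipe run rec.csv --out results/
crtpipe demod-selftest
```

`crtpipe run` writes `refills.csv`, `series.csv`, `stats.json` and a
`manifest.json` recording configuration, input hashes and per-stage counts.

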