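# Methods

## The measurement

An automated CRT device blanches the capillary bed by inflating a small cuff
against the skin to ~17 kPa (130 mmHg, safely above systolic pressure) for
7 s, then vents it through a solenoid valve. Diffuse reflectance rises by
tens of percent while blood is expelled (most strongly at 520 nm, near a
haemoglobin absorption peak) and decays back to baseline as the capillaries
refill. The capillary refill time is the duration of that decay, made
precise by a fractional-threshold rule (below). Cycles repeat every 23 s, so
the device produces a quasi-continuous CRT series together with cuff
pressure and skin-surface temperature.

## Pipeline model and assumptions

**Release detection.** A release is the first sample with pressure below
3.1 kPa after the pressure has stayed above 3.5 kPa for at least 1 s. The
hold requirement is evaluated against the upper threshold (the stricter of
the two readings of "remained above that level"; during a normal hold the
cuff sits near 17 kPa, so the distinction rarely matters). Once armed, dips
into the 3.1–3.5 kPa band do not disarm the detector; only a firing release
resets it. Release times are sample-aligned (no sub-sample interpolation) —
sub-sample precision matters only at the CRT threshold crossing, which does
interpolate.

**Two-part fit.** Each 10 s post-release window is modelled as a quadratic
(the refill) on `[0, t*]` joined to a straight line (the baseline) on
`[t*, 10 s]`. The transition `t*` is scanned on a grid of one optical sample
period (~16.1 ms, the finest grid the data supports) over 1–6 s; the pooled
RMS of the residuals from both fits selects `t*`. The boundary sample
belongs to both regions. The scan is solved by batched normal equations from
prefix/suffix power sums, with residuals evaluated directly for numerical
accuracy; the reported optimum is refit with ordinary least squares.

**Rejection rules**, checked in order, first hit wins:

1. `rms_error > max_rms_error` — pooled RMS at the optimum;
2. `region1_mean_slope > 0` — the refill must be net-decreasing; the slope
   is the secant slope of the quadratic over region 1 (mean of its
   derivative). A strict-positivity tolerance of 1e-9 counts/s absorbs float
   round-off on flat segments. A config switch
   (`refill_slope_from_line`) selects the alternative reading — a separate
   straight-line fit to region 1;
3. `|baseline_slope| > max_baseline_slope` — too much drift;
4. `no_crossing` — an accepted fit whose raw trace never reaches the
   threshold level (a case the published procedure leaves unspecified; a
   dedicated reason keeps it auditable).

**Threshold CRT.** The baseline at release is the region-2 line extrapolated
to t = 0; the initial height is the first window sample minus that baseline.
CRT is the first time the *raw* intensity falls below
`baseline + level × initial_height`, located by linear interpolation between
the bracketing samples ("intensity first fell" refers to the data, not the
fit). Default threshold level 0.20; 0.35 is the conventional alternative and
yields uniformly shorter CRTs on monotone refills.

**Conditioning.** Accepted CRTs are linearly interpolated onto a uniform
0.1 Hz grid and filtered with a 2 mHz second-order Bessel low-pass applied
forward then backward (zero net phase, magnitude response squared — so a
sinusoid at the cut-off emerges at half amplitude). At 520 nm an additional
0.5 mHz stage is cascaded by default ("also applied" read as cascade, not
replacement; `cascade_520=False` selects the other reading). The cut-offs
reflect clinical practice: manual CRT at 15-minute intervals has a Nyquist
frequency of ~0.55 mHz. The discretisation is bilinear, which pins DC gain
at exactly 1; edges use odd reflection padding of at least three filter time
constants. Gaps between used refills longer than five cuff cycles (115 s)
are not interpolated across — the series is split into independently
filtered blocks, because bridging long dropouts fabricates data. Blocks
shorter than the padding are passed through unfiltered with a logged notice.

**Statistics.** Inverse CRT (1/CRT, so that a healthy sensor yields a
positive r) is paired with the spot temperature at the release sample, using
raw unfiltered CRTs from used refills only. Pearson r carries a Fisher-z′
95% CI (`z′ = atanh r`, SE `1/√(n−3)`); significance means the CI excludes
zero (two-sided p < 0.05); no multiple-testing correction is applied, since
the validation design applies none. |r| = 1 is flagged degenerate (infinite
z′). Binned densities use half-open bins of 0.1 s × 0.25 °C anchored at
zero; best-fit lines are ordinary least squares through the *unbinned*
points (the statistically cleaner reading; bin-centre fitting is not
offered). `percent_per_degree` expresses a fit slope as a percentage of a
reference CRT.

## The simulator

The simulator emulates the study conditions, not microcirculation
biophysics: per cycle it ramps pressure over 1 s, holds 7 s at 17 kPa, and
vents exponentially (τ = 0.15 s) to a 0.2 kPa residual, as residual pressure
remains visible after release on real traces. Blanching raises each optical
channel by `blanch_gain × baseline` (defaults 0.60 / 0.15 / 0.20 at
520/640/950 nm over a 1000-count baseline — the 520 nm rise matching the
~60% seen in practice); the refill decay starts at the exact analytic
instant pressure crosses 3.1 kPa, the same event the segmenter detects, so
ground truth and extraction share a time origin to within one sample.

The true refill shape is unknown (published procedures characterise it only
through the fitted quadratic), so the decay `g` is a modelling choice:

- **quadratic plateau** (default): `g(x) = (1 − x/2)²` for x < 2, then 0.
  Finite support makes the two-part model exactly realizable: the baseline
  fit is uncontaminated and the fractional-threshold CRT
  `2τ(1 − √L)` is recovered analytically. Noise-free end-to-end recovery is
  within one sample period; this realizability is what makes ground-truth
  recovery a meaningful test of the *pipeline* rather than of shape
  mismatch.
- **exponential** (`refill_shape="exponential"`): `g(x) = e^(−x)`, CRT
  `τ ln(1/L)`. Its infinite tail leaks into the baseline region, biasing the
  extrapolated baseline and hence the extracted CRT by ~0.1 s at default
  parameters even without noise. It is retained as the deliberate
  stress-test of model mismatch, not as the default study condition.

Ground-truth CRT is defined at a reference threshold level (default 0.20)
and modulated multiplicatively by temperature:
`crt(T) = crt_ref (1 + s (T − T_ref))`, sensitivity `s` in fractional change
per °C (default −0.07, i.e. ~7% longer per °C of cooling, the magnitude
published manual-CRT temperature studies report). Confounds: linear baseline
drift (default 0), cardiac sinusoid (1.2 Hz; 5 counts at 520 nm, 1
elsewhere — real traces show a cardiac-synchronous component mainly at
520 nm), white noise (default 10 counts = 1% of baseline), and Poisson-timed
motion artifacts (step / spike / 5 s tilt). A single integer seed drives all
randomness; ground truth is emitted alongside the recording, never
re-derived from it.

What the simulator does **not** emulate: pulse-shaped (non-sinusoidal)
cardiac waveforms, ambient-light interference, autogain behaviour,
skin-tone-dependent signal levels, correlated (pink) sensor noise, or any
vasomotor dynamics. Passing tests therefore demonstrate correctness of the
algorithmic chain under controlled conditions, not clinical performance.

## Demodulator conventions

The carrier scheme is parameterised in integer DFT-bin units so that
orthogonality holds by construction: ADC rate 46,680 Hz, window 752 samples,
centre bin 188, giving a spacing of 46,680/752 = 62.074 Hz and a centre of
exactly 11,670 Hz (the hardware's published values to within 0.06%; the
original clock-tree-derived rates are not recoverable from the published
description). Carriers are sinusoidal by default (square-wave drive
available; its recoverable fundamental is 4/π of the peak amplitude); DFT
windows are rectangular and non-overlapping. PWM gating jitter is out of
scope — its consequence, inter-channel cross-talk, is covered by the leakage
tests. The ENOB model is implemented in its simplified form
`18.9 − 0.72 ln Δf`, which reproduces the quoted 17.2 bits at Δf = 10 Hz;
the unsimplified printed expression `ln(4.9×10⁵/Δf)/ln 2` is inconsistent
with the simplified one unless the bandwidth enters under a square root
(noise ∝ √Δf), a discrepancy we note rather than resolve.

## Calibrated parameters

`max_rms_error` and `max_baseline_slope` have no published values (they were
tuned by visual inspection on the original data), so the defaults are
calibrated once against the simulator's default study conditions:

- `max_rms_error = 12.5` counts: the clean-simulation pooled RMS is
  10.5 ± 0.33 counts (1% noise plus unfitted cardiac ripple); the default
  sits ~6 SD above the clean mean, keeping > 99.9% of clean refills while
  flagging any systematic residual structure above roughly half the noise
  floor.
- `max_baseline_slope = 10` counts/s: 1% of the nominal 1000-count baseline
  per second.

Both are ordinary config entries and are logged with every run (the manifest
snapshots the full configuration).

## Numerical choices

- Transition-scan ties: `argmin` keeps the earliest grid transition.
- The uniform-grid invariant is 1 ppm relative to 1/sample_rate; CSV output
  therefore stores time at full precision while data channels round to 6
  significant digits (the lossless reference format is HDF5).
- Missing values are NaN internally and empty fields in CSV, never zero.
- Degenerate inputs fail loudly with typed errors (schema / insufficient
  data / config), which the CLI maps to exit codes 2/3/4.
- Acceptance-scale runs use ~300 refills (noisy recovery) and 15 subjects ×
  205 refills (cohort recovery) — sizes at which the binomial and CI
  calibration checks are well resolved.
- The noisy recovery and cohort checks are evaluated on the 520 nm channel,
  the device's primary CRT channel: its ~60% blanching modulation gives a
  threshold-crossing slope steep enough for sub-50 ms timing; at the 640/950
  nm modulation depths (~15–20%) the first-crossing rule on raw data has a
  noise-induced early bias of order 100 ms at 1% noise.

## Known limitations

- **Step artifacts can be invisible to the rejection rules.** The transition
  scan may place `t*` at the step itself, absorbing it into the two-part
  model: a step landing at or just after the true refill end yields a fit
  error indistinguishable from clean data at *any* amplitude, and a modest
  step during the decay is largely absorbed by the free quadratic. The
  published rejection rules (RMS error, refill slope, baseline drift) catch
  mid-baseline steps reliably but not transition-coincident or very late
  ones; the extracted CRT of such absorbed refills is biased through the
  shifted baseline. Measured on default conditions with 5-σ steps: ~0%
  rejection for steps in the first 3 s, ~100% beyond 6 s.
- The first-crossing CRT on raw data is biased early under noise; the
  published procedure measures on raw data, and smoothing first would trade
  bias for lag.
- The CSV schema stores pressure and temperature on the optical grid; real
  hardware may subsample them, in which case they must be upsampled on
  ingest.
- Correlation CIs treat refills as independent samples; consecutive refills
  23 s apart are physiologically autocorrelated, so real-data CIs are
  somewhat anti-conservative. The validation design shares this property.
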