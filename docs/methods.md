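# Methods

## Scope and model

`vitalink` is a desk-scale re-creation of the computational chain of an
IoT vital-sign monitor: a dual-wavelength pulse oximeter plus a digital
thermometer feeding a microcontroller that encrypts each reading and ships
it to a cloud store, from which a clinician-side consumer decrypts it. The
physical sensors are replaced by a generative model with known ground
truth; everything downstream (signal processing, secure payload, agreement
statistics) operates exactly as it would on real device output.

### Photoplethysmography model

A PPG channel is modelled as

    x(t) = DC · (1 + a · s(t)) + ε(t),    ε ~ N(0, σ²) i.i.d.

where `DC` is the non-pulsatile intensity (reflections from bone, tissue
and other stationary structures), `s(t)` a zero-mean periodic pulse
waveform normalized to unit peak-to-peak amplitude at the beat frequency
f₀ = HR/60, and `a` the channel's perfusion index — the AC/DC ratio, AC
measured peak-to-trough. The default pulse shape is a fundamental plus a
0.3-amplitude second harmonic with phase offset π/4, a minimal caricature
of the systolic upstroke and dicrotic notch; the shape is a replaceable
callable but this is the tested default.

SpO₂ enters through the ratio of ratios

    R = (AC/DC)_red / (AC/DC)_ir

and an empirical calibration line SpO₂% = intercept − slope·R, presets
`classic` (110 − 25R) and `maxim` (104 − 17R, the MAX30102 vendor
calibration; the default since that is the sensor family being emulated).
The simulator sets the IR perfusion index directly and scales the red one
by R⁻¹-inverted calibration, so the extraction chain has an exact target.
Both presets map the physiological SpO₂ range to R > 0; requesting an
unattainable saturation (e.g. above the line's intercept) is a parameter
error.

### Extraction chain

* **Baseline / DC**: moving average over twice the longest admissible beat
  period (2 × 60/min_hr, default 4 s); DC is its mean. The pulsatile
  component is the remainder.
* **Peak detection**: local maxima of the lightly smoothed (50 ms moving
  average) pulsatile signal with minimum separation 60/max_hr and
  prominence ≥ 0.3 × the window's pulsatile peak-to-peak range. The signal
  is mirror-padded by one longest beat so boundary beats keep their full
  prominence. Each peak is refined to sub-sample time by a quadratic
  least-squares vertex fit over a ±quarter-beat window: without
  refinement, peak times are quantized to the sample grid (≈2 bpm error at
  180 bpm and 100 Hz alone) and the raw argmax of a flat-topped pulse
  jitters by tens of milliseconds under noise.
* **Heart rate**: 60 / median inter-peak interval. The median makes a
  single missed or spurious beat inert (intervals {0.8, 0.8, 2.0} s still
  give 75 bpm). Fewer than two peaks is an insufficient-signal error; a
  flat window yields an empty, flagged peak train.
* **Beat frequency for amplitude estimation** is obtained spectrally:
  dominant rFFT bin inside the admissible band, then a bounded scalar
  search maximizing the sinusoidal projection amplitude. Interval-based
  estimates lose end-to-end phase coherence over a 30 s window when a
  single beat is missed (a 1 % frequency error drifts > 1 cycle over the
  window), which collapses the harmonic fit; the spectral estimate does
  not care about missed beats.
* **AC amplitude** (default `method="harmonic"`): least-squares projection
  of the pulsatile signal onto sin/cos pairs at f₀ and 2f₀, reporting the
  peak-to-trough of the reconstruction. The projection is linear in the
  data, so additive white noise averages out over the window instead of
  inflating the extremes: a direct per-beat max-minus-min estimator is
  biased upward by order σ√(2 ln n) per extreme, which at 1 %-of-DC noise
  exceeds the red channel's whole AC amplitude and would bias SpO₂ by
  2–3 percentage points. A `method="per_beat"` estimator (median
  peak-to-trough across detected beats) is retained for clean signals and
  cross-checks the harmonic one at 0.5 % on noiseless windows. Half a
  baseline window is trimmed at each end before fitting, where the moving
  average is edge-distorted. Both channels use the same f₀ and the same
  amplitude convention, so any residual shape attenuation cancels in R.
* **SpO₂**: calibration line applied to R, clamped to [0, 100] with a flag
  (the linear approximations exceed 100 % at small R; saturation is
  physically bounded, so clamping is not an error).
* **Temperature**: readings are quantized to the nearest multiple of the
  sensor resolution (12-bit default, 0.0625 °C), ties away from zero. The
  synthetic thermometer adds a truncated-Gaussian error (SD = bound/2,
  truncated at ±bound, default bound 0.5 °C) before quantization — the
  emulated part's datasheet states only an accuracy bound and a
  resolution, so this is the least-structured model consistent with both.

### Secure payload

Records serialize to fixed-order `key:value` lines (subject, timestamp,
integer HR and SpO₂, temperature at 4 decimals); serialization
canonicalizes, so round-trip identity holds for records on that grid.
Payloads are PKCS#7-padded, encrypted with AES-128 in CBC mode and
Base64-encoded (RFC 4648, no wrapping). The cipher is implemented
in-package with the S-box derived from the GF(2⁸) multiplicative inverse
plus the standard affine map, and is pinned byte-exactly to the published
single-block and multi-block known-answer vectors in the test suite;
correctness rests on those vectors, not on prose. Every message uses a
fresh random 16-byte IV stored beside the ciphertext. A wrong key or a
corrupted ciphertext surfaces uniformly as an authentication failure —
never a partial record. The cloud is an in-process key-value store holding
ciphertext only; the telemetry loop runs on a virtual clock (default
period 5 s, configurable) so periodic sending is testable without
sleeping, and per-record corruption is isolated rather than fatal to the
stream.

### Agreement statistics

For K pairs (measured, reference), with d_i = measured_i − reference_i:

* RMSE = √(Σ(ref−mes)²/K), MAE = Σ|ref−mes|/K,
  MRE = (1/K)Σ|ref−mes|/ref (reported both as a fraction and ×100 as a
  percent — the source tables use both scales for the same quantity).
* Per-reading percent error 100·|mes−ref|/ref, rounded to 2 d.p. for
  display only.
* OLS of reference on measured; R² is the squared Pearson correlation.
  This definition is deliberate: a device can read within ~1 % of the
  reference yet show R² near zero when the underlying quantity barely
  varies across subjects, which is exactly the packaged SpO₂ table
  (readings confined to 97–100 %, R² ≈ 0.075). An identity-line
  R² (1 − SSres/SStot) would conflate accuracy with between-subject
  spread.
* Bland–Altman: differences d_i against pair averages, 95 % limits of
  agreement mean(d) ± 1.96·SD(d). SD uses the sample convention
  (divisor K−1) by default; the divisor is configurable and recorded in
  the result. Points strictly beyond either limit are counted. On the
  packaged tables the counts are 0 (heart rate), 3 (SpO₂) and
  1 (temperature) — i.e., containment of *all* points holds only for the
  heart-rate table, and the corresponding acceptance test documents the
  containment claim and fails it for the other two rather than adjusting
  the limits.
* All statistics are computed at full precision; table-style rounding is
  display-only. An independent plain-loop implementation in the test
  suite pins every statistic to 1e-12 relative on 1 000 random tables.

## Study conditions and defaults

| parameter | default | why |
|---|---|---|
| sampling rate | 100 Hz | typical pulse-oximeter configuration; ≥ 2× the highest modelled harmonic at 220 bpm |
| window length | 30 s | a few dozen beats at resting rates; enough spectral resolution to pin f₀ to ≪ 1 bin |
| IR perfusion index | 0.05 | strong-but-plausible fingertip pulsatile fraction |
| DC levels (red, IR) | 0.9, 1.0 | arbitrary intensity units; unequal on purpose so channel mix-ups cannot cancel |
| noise SD | 0 (clean) / 0.01 = 1 % of IR DC (stress) | the two conditions the recovery sweep exercises |
| calibration | maxim | sensor family being emulated; classic selectable everywhere |
| temperature accuracy / resolution | ±0.5 °C / 0.0625 °C | emulated thermometer datasheet values |
| heart-rate admissible band | 30–220 bpm | generous physiological range; bounds the peak separation and the spectral search |
| send period | 5 s | device behaviour; configurable |

Problem sizes used by the test suite and `scripts/acceptance.py` — 100
simulation windows per noise condition, 1 000 random tables for the
statistics oracle, 100 records for the encryption round trip — keep a full
run in seconds while leaving the empirical margins (worst-case HR error
≈ 1.5 bpm of a 2 bpm budget, SpO₂ ≈ 0.9 pp of 1 pp at the noisy
condition) visible rather than averaged away.

## What the generator does and does not emulate

The simulator produces stationary, strictly periodic pulses with additive
white Gaussian noise of equal SD on both channels. Real PPG adds baseline
wander, motion artifacts, ambient-light steps, beat-to-beat period and
amplitude variability, and channel-dependent noise; none of these are
modelled, and the sensor's own DSP (ambient cancellation, LED current
control) is out of scope. Passing the recovery sweep therefore shows the
chain is correct and noise-robust under the stated model — not that it is
field-ready on ambulatory data. The agreement suite, by contrast, runs on
real printed device-versus-reference readings and carries no such caveat.

## Numerical choices and degenerate inputs

* Quantization ties round away from zero (36.6875 ± half a step moves
  outward), so a reading exactly between grid points never rounds down on
  magnitude.
* Zero-variance (flat) windows yield an empty flagged peak train; heart
  rate then raises an insufficient-signal error tagged with the pipeline
  stage; pure-DC channels yield AC = 0, making R undefined (an error) only
  when the IR AC is zero.
* The harmonic fit drops its constant column when reconstructing, so any
  residual DC leakage in the pulsatile remainder cannot inflate AC.
* SpO₂ clamping is flagged, not silent, and the pre-clamp value is kept.
* Bland–Altman "outside" is strict inequality; with all-zero differences
  the limits collapse to [0, 0] and nothing is outside.

## Known limitations

* The per-beat AC estimator is noise-biased by construction and is only
  recommended for clean signals; it exists as a cross-check.
* The first and last detected beats sit on the baseline's edge region and
  can be shifted by a few tens of milliseconds; the median-based heart
  rate ignores this, but single-beat analyses should trim edges.
* The pure-Python cipher is written for auditability, not throughput
  (~thousands of blocks per second); payloads here are tens of bytes.
* Key management is out of scope: keys are static files, and there is no
  authentication layer beyond the implicit padding check, which is not a
  MAC — a production system would use authenticated encryption.
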