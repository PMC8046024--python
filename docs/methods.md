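# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `speechdpoae`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from external data.

## Signal model

Voiced speech is modelled as a harmonic complex: a fundamental frequency
f0(t) between 40 and 400 Hz with higher harmonics at k·f0(t). The
*fundamental waveform* w0(t) isolates the fundamental: the speech is
bandpass-filtered around its mean f0 over voiced frames, with the passband
spanning 0.5 SD below to 0.5 SD above the mean, and unvoiced stretches are
set exactly to zero. The waveform tracking the n-th harmonic is obtained by
analytic-signal frequency shifting,

    W0(t) = w0(t) + i·H[w0(t)],      wn(t) = |W0(t)|·cos(n·arg W0(t)),

which preserves the amplitude envelope while multiplying the instantaneous
frequency by n. Playing wm and wn (m < n) into a compressively nonlinear
ear produces cubic distortion tracking harmonics 2m−n (lower sideband, the
strongest in human ears and the one analysed here) and 2n−m.

The detector is the normalized complex cross-correlation

    C(τ) = N · Σ_t r(t+τ) · (w(t) + i·H[w(t)]),    N = 1/(‖r‖·‖w‖),

where w is the lower-sideband template. With this N, correlating the
template with itself gives amplitude exactly 1 at zero lag, `|C| ≤ 1`
everywhere (Cauchy–Schwarz within the span of w and H[w]), and a recording
equal to H[w] reads phase +π/2. Positive lag means the recording's content
follows the template. An emission injected with delay d and phase lag φ
(i.e. `|W(t−d)|·cos(arg W(t−d) − φ)`) is read back as a peak at lag d with
correlation angle +φ.

## Processing parameters

| parameter | default | role |
|---|---|---|
| sampling rate | 44.1 kHz | audio and correlogram grid |
| bandpass order | 6 (designed; forward–backward doubles the effective order) | fundamental isolation |
| passband | mean f0 ± 0.5·SD (Hz) | fundamental isolation |
| voicing ramps | 20 ms raised cosine | gate transitions (see below) |
| edge trim | 3 s per end | removes onset/offset transients |
| envelope smoothing | 199 samples (4.5 ms) moving average, reflect padding | peak stabilisation |
| noise windows | lags ±(70–750) ms | 95th-percentile noise floor |
| peak window | lags 0–7 ms | emission search |
| harmonic pairs | male 9/11 (template 7), female 6/8 (template 4) | primary ratio ≈ 1.2 / 1.33 |
| pure-tone primaries | f1 = 1 kHz, f2 = 1.2 kHz | conventional reference |
| bootstrap | 10,000 resamples, percentile CI | group inference |

The pitch tracker (40-ms frames, 10-ms hop, 40–400 Hz search, voicing
threshold 0.45 on the normalized autocorrelation peak) stands in for an
external pitch analysis; a pitch track can equally be supplied as a
`time_s,f0_hz` CSV. Among near-equal autocorrelation peaks the shortest lag
wins, which suppresses octave errors; the period is refined by parabolic
interpolation.

**Voicing ramps.** The gate separating voiced from unvoiced stretches uses
raised-cosine ramps that live entirely inside each voiced run, so unvoiced
samples are exactly zero. The default ramp is 20 ms: the eliciting
harmonic wm and the template w\_{2m−n} differ in instantaneous frequency by
(n−m)·f0 ≈ 2·f0 ≈ 210 Hz, and a 5-ms ramp places enough envelope sideband
energy at that beat frequency that the stimulus itself bleeds into the
template correlogram at the 10⁻⁴ level — comparable to a genuine emission,
and contrary to the empirical observation that the stimulus alone produces
no emission-band peak. At 20 ms the bleed-through falls to ~10⁻⁶, well
below the noise floor. For the same reason, whenever a waveform is *cut*
(the 3-s trim, the 10-interval split of the attention analysis), the cut
template is re-tapered with 20-ms edges before correlating.

**Zero-phase filtering.** The bandpass runs forward and backward
(`sosfiltfilt`), so it introduces no group delay; the padding length scales
with the filter's transient time constant (~fs/(π·half-bandwidth) samples,
times 22) so that edge transients decay below 1e−9 and filtering commutes
with time reversal to that tolerance.

**Tie-breaks and degenerate inputs.** The peak search returns the earliest
lag among equal maxima. An insignificant emission is a returned result,
never an exception. All-zero templates, zero-variance pitch tracks
(degenerate passband), even smoothing windows, all-tied group samples and
sub-second attention intervals raise errors.

## The virtual ear

`EarModel` maps a stimulus pair to a microphone recording:

    r(t) = passthrough_gain·(wm + wn)(t) + distortion(t) + noise,

with white Gaussian noise (default RMS 1e−3 full scale) and one of two
distortion channels:

- **inject** (default): `gain · |W(t−d)|·cos(arg W(t−d) − φ)` — the
  lower-sideband template re-emitted with exact, known amplitude, latency
  (default d = 2.2 ms, the observed emission delay) and phase. This gives
  ground truth for calibration.
- **cubic**: a memoryless x³ applied to the stimulus sum, band-limited
  below a quarter of the sampling rate with a zero-phase lowpass. For unit
  two-tone input the 2f1−f2 line has amplitude exactly 3/4 (verified
  against a symbolic product-to-sum expansion); all other lines appear only
  at the predicted intermodulation frequencies.

`SpeechLikeSpec` synthesizes speech-like stimuli: harmonics with 1/k
amplitude rolloff on a common phase path ∫f0 dt, alternating voiced
stretches (0.8–2 s) and unvoiced noise gaps at a target voiced fraction
(default 0.7), and a fundamental that wanders as band-limited Gaussian
drift (2-Hz cutoff, SD clipped at 3σ) around speaker-like means — male
105 ± 6 Hz, female 172 ± 10 Hz. Random prosodic drift, rather than a
deterministic vibrato, is what makes the correlogram envelope decorrelate
over milliseconds so that the emission latency is localizable at all.

**Default operating point.** The inject gain (5e−4) puts the detected
normalized correlation amplitude at ~3.5e−4, the scale reported for human
ears, with a noise floor roughly forty times lower — a deliberately clean,
well-sealed-probe regime chosen so that ground-truth recovery (latency,
phase, attentional gain ratio) is sharp. Real ear-canal recordings sit much
closer to their noise floors; passing the recovery tests here demonstrates
correctness of the measurement chain, not that real data will yield
per-subject modulation estimates at ±0.02 precision.

## What the tests show, and what they cannot

- **Oracle equivalence.** The FFT-based correlation equals a direct
  lag-loop evaluation to 1e−10 (relative to the largest correlation value)
  on 1,000-sample signals.
- **Closed forms.** Harmonic shifting of a constant-amplitude tone matches
  A·cos(2πnft) to better than 1e−3 relative RMS; n = 1 returns w0
  bit-exactly; envelope conservation and phase composition hold to the
  tolerances of the analytic-signal construction.
- **Parameter recovery (noise-free, emission only).** Injected latencies
  0.5–6.5 ms are recovered with median error far below half the smoothing
  window; eight phase lags are recovered within 0.1 rad; detected amplitude
  is linear in injected gain (R² > 0.99). These calibrations exclude the
  stimulus passthrough because the smoothed correlation envelope of these
  narrowband templates is nearly flat across the 0–7 ms window: its
  curvature there is a fraction of a percent, so any perturbation of
  comparable size (noise, residual stimulus bleed) legitimately moves the
  argmax by milliseconds. Amplitude, by contrast, is robust — which is why
  the attention analysis is amplitude-based and reads interval amplitudes
  at a fixed segment-level latency.
- **False-positive calibration.** On 200 pure-noise recordings the
  significance rule fires at roughly its nominal level. Two finite-size
  effects matter. First, recording length: at short lengths the template
  overlaps the recording less at far lags than near zero lag, which
  deflates the noise floor and inflates the rate (measured 11.5% at 12 s);
  the calibration therefore uses 48-s recordings, where the artifact is
  largely gone (full-length 114-s recordings are cleaner still: pointwise
  exceedance 3.5%). Second, the 0–7 ms search spans slightly more than one
  correlation cell of the smoothed envelope, and the floor itself is
  estimated from a limited number of independent cells, so the windowed
  rate sits a few points above the pointwise 5% (measured 6–10% across
  stimulus and noise seeds at 48 s; ~7.5% at 114 s); this is a property of
  the procedure itself, not of the implementation.
- **Attention recovery.** Simulated attended/ignored pairs with gain ratio
  g have expected modulation 2(g−1)/(g+1). Six 120-s pairs at g = 1.066
  recover the mean within ±0.02 of 0.064, and g = 1 yields |A| < 0.02. The
  stimulus bleed that survives tapering is common to both conditions and
  largely cancels in A.
- **Bootstrap behaviour.** With 17 subjects drawn from Normal(0.064, 0.12)
  — an effect size and spread typical of small attention experiments — the bootstrap mean tracks the
  sample mean, whose sampling SD is 0.12/√17 ≈ 0.029 by the CLT. Recovery
  is therefore asserted at the 2σ band (±0.06 in ≥90% of replications);
  demanding ±0.03 would fail ~30% of the time for any correct estimator.
  Under a zero-mean population the one-sided bootstrap p-value is uniform
  to within Kolmogorov distance 0.1.

The simulator does **not** model: cochlear transmission-line mechanics or
two-component (short/long latency) emission generation, efferent dynamics
(the attentional gain ratio is static), middle-ear muscle reflexes,
realistic ear-canal noise spectra (noise is white), formants or consonant
spectra in the stimulus, or absolute sound-pressure calibration (all
amplitudes are digital full scale; levels are relative gains).

## Problem sizes

Defaults match the measurement protocol the package implements: 120-s speech segments at 44.1 kHz
(trimmed to 114 s), 2-min attention pairs, 10 intervals per segment,
10,000 bootstrap resamples. The acceptance script uses 20-s segments for
noise-free calibration sweeps, 48-s recordings for the 200-run
false-positive calibration, and three 120-s segments × two ears per
condition for attention recovery; these sizes are stated here as the
package's own choices for routine verification runs.

## Open design choices made

- Normalization uses the real template's energy, making the template
  autocorrelation exactly 1 at zero lag; normalizing by the analytic
  template's energy (≈2× the real energy) would scale all amplitudes by
  ≈1/√2.
- The noise floor is computed on the smoothed envelope — the same
  processing the signal region receives.
- The equipment delay is the mean of the two eliciting-waveform delays,
  with a warning when they disagree by more than 0.5 ms; a waveform is
  declared present when its correlation peak exceeds 0.1 (stimuli dominate
  genuine recordings with peaks of order one, while noise-only correlations
  are orders of magnitude lower).
- Bootstrap confidence intervals are percentile intervals; the one-sided
  p-value is the fraction of resampled means at or below zero.
- Outliers for the group-test rerun follow the 1.5×IQR rule.
- Subject exclusion (non-significant emissions, explicit lists) is a
  configurable filter on the subject table, not hard-coded.
- Eliciting waveforms are scaled in relative digital units; a relative gain
  parameter stands in for absolute SPL calibration, which requires
  hardware.
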