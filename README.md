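# speechdpoae

Tools for measuring **distortion-product otoacoustic emissions evoked by
running speech** (speech-DPOAEs), together with the statistics used to ask
whether selective attention modulates them, and a virtual-ear simulator that
makes every stage testable without human recordings.

## The problem and the method

The cochlea amplifies sound through an active, compressively nonlinear
mechanism. Driving an ear with two tones f1 < f2 makes this nonlinearity
radiate faint sound back into the ear canal at the cubic
distortion frequencies 2·f1 − f2 and 2·f2 − f1 (distortion-product
otoacoustic emissions, DPOAEs). Pure tones, however, say nothing about how
the cochlea handles speech, whose harmonics move with the speaker's
fundamental frequency f0(t).

This package implements the speech-matched analogue:

1. **Fundamental waveform.** The speech signal is bandpass-filtered around
   its mean f0 (passband `mean ± 0.5·SD`, zero-phase 6th-order Butterworth),
   and zeroed on unvoiced stretches, giving w0(t).
2. **Harmonic shifting.** From the analytic signal
   `W0(t) = w0(t) + i·H[w0(t)]` (Hilbert transform H), the waveform tracking
   the n-th harmonic is `wn(t) = |W0(t)|·cos(n·arg W0(t))`. Two such
   waveforms wm, wn (male voice: 9th and 11th harmonics; female: 6th and
   8th) are played into the ear and elicit cubic distortion at the
   instantaneous frequencies (2m−n)·f0(t) and (2n−m)·f0(t).
3. **Detection.** The microphone recording r(t) is compared with the
   lower-sideband template w\_{2m−n}(t) through a normalized complex
   cross-correlation

       C(τ) = N ∫ r(t + τ)·{w(t) + i·H[w(t)]} dt,

   with N chosen so the template's autocorrelation amplitude is 1 at zero
   lag. The envelope |C| is smoothed (199-sample moving average); the noise
   floor is the 95th percentile of the smoothed envelope at lags ±(70–750)
   ms; the emission is significant when the 0–7 ms peak exceeds it. Latency
   and phase are read at the peak.
4. **Attention statistics.** For paired recordings of the same segment with
   the voice attended versus ignored, the relative attentional modulation is
   `A = 2(r_A − r_I)/(r_A + r_I)`, averaged per subject, tested with
   Wilcoxon signed-rank and a 10,000-resample bootstrap of the mean.

A pure-tone DPOAE module (spectrum and cross-correlation analyses at
f1 = 1 kHz, f2 = 1.2 kHz) provides the conventional reference measurement,
and `speechdpoae.simulate` provides speech-like stimuli with known pitch
plus a virtual ear (memoryless x³ channel, or direct injection of the
emission with known gain, latency and phase).

## Worked example

```python
import speechdpoae as sd

# synthesize 40 s of male-like speech (f0 = 105 ± 6 Hz) with known pitch
spec = sd.SpeechLikeSpec(duration_s=40.0, seed=6)
speech, pitch = sd.synth_speechlike(spec)

# eliciting pair (9th/11th harmonics) and lower-sideband template (7th)
w0 = sd.extract_fundamental(speech, pitch)
stimuli = (sd.harmonic(w0, 9), sd.harmonic(w0, 11))
template = sd.distortion_template(9, 11, w0, "lower")

# virtual ear injects the emission 2.2 ms after the stimulus
# (simulated recordings have no onset transients, so no edge trim is needed;
# run_detect applies the 3-s trim and equipment-delay compensation for files)
rec, truth = sd.simulate_recording(stimuli, sd.EarModel(seed=2), template=template)

c = sd.smooth_envelope(sd.complex_xcorr(rec, template, max_lag_s=0.75), 199)
floor = sd.noise_floor(c)
res = sd.find_peak(c, floor)
print(f"peak {res.peak_amplitude:.2e} at {res.latency_s*1e3:.1f} ms, "
      f"floor {floor:.2e}, significant={res.significant}")
```

This prints:

```
peak 3.56e-04 at 4.0 ms, floor 5.99e-05, significant=True
```

i.e. a clearly significant emission with a normalized correlation amplitude
of a few 10⁻⁴ — the scale observed in human ears — about six times the
noise floor. (The peak-lag readout is only millisecond-sharp when
measurement noise is far below the emission; see `docs/methods.md`.)

The same chain is available from the shell:

```bash
speechdpoae simulate --duration 120 --seed 5 -o sim
speechdpoae detect sim_stimulus.wav sim_recording.wav --pitch sim_pitch.csv -o out
speechdpoae puretone recording.wav --f1 1000 --f2 1200 -o puretone.tsv
speechdpoae attention subjects.tsv -o report.json
```

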