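"""Emission detection by normalized complex cross-correlation.

The microphone recording r(t) is compared against the expected distortion
waveform w(t) through

    C(tau) = N * sum_t r(t + tau) * (w(t) + i*H[w(t)]),

with N chosen so that correlating the template with itself gives amplitude 1
at zero lag (N = 1 / (||r|| * ||w||), a complex Pearson-style coefficient).
A positive lag means the recording's content follows the template.  The
envelope |C| is smoothed with a 199-sample moving average; the noise floor is
the 95th percentile of the smoothed amplitude over lags of +-(70-750) ms, and
an emission is significant when the smoothed peak within 0-7 ms exceeds it.
The phase at the peak lag is read from the unsmoothed complex value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import correlate

from ._dsp import analytic_signal, moving_average
from .signals import HarmonicWaveform, MicRecording

__all__ = [
    "ComplexCorrelogram",
    "DPOAEResult",
    "complex_xcorr",
    "smooth_envelope",
    "noise_floor",
    "find_peak",
    "estimate_equipment_delay",
    "preprocess",
]

PEAK_WINDOW_S = (0.0, 0.007)
NOISE_WINDOW_S = (0.070, 0.750)
SMOOTHING_LEN = 199


@dataclass
class ComplexCorrelogram:
    """C(tau) on a symmetric lag grid, with optional smoothed envelope."""

    lags_s: np.ndarray
    values: np.ndarray
    normalization_N: float
    rate_hz: float
    smoothed_amplitude: np.ndarray | None = None
    smoothing_len: int | None = None

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass
class DPOAEResult:
    """Peak of the correlogram within the emission search window."""

    peak_amplitude: float
    latency_s: float
    phase_rad: float
    noise_floor: float
    significant: bool
    search_window_s: tuple[float, float] = PEAK_WINDOW_S


def complex_xcorr(
    rec: MicRecording, template: HarmonicWaveform, max_lag_s: float = 0.75
) -> ComplexCorrelogram:
    """Normalized complex cross-correlation of a recording with a template."""
    if rec.rate_hz != template.rate_hz:
        raise ValueError("recording and template sampling rates differ")
    w = template.samples
    r = rec.samples
    norm_w = float(np.linalg.norm(w))
    if norm_w == 0.0:
        raise ValueError("all-zero template: normalization undefined")
    norm_r = float(np.linalg.norm(r))
    if norm_r == 0.0:
        raise ValueError("all-zero recording: normalization undefined")
    fs = rec.rate_hz
    n_lag = int(round(max_lag_s * fs))
    if n_lag >= w.size or n_lag >= r.size:
        raise ValueError("signals too short for the requested maximum lag")
    a = analytic_signal(w)
    # correlate(r, conj(a))[len(a)-1 + tau] = sum_t r(t + tau) * a(t)
    full = correlate(r, np.conj(a), mode="full", method="fft")
    zero = a.size - 1
    N = 1.0 / (norm_r * norm_w)
    values = full[zero - n_lag : zero + n_lag + 1] * N
    lags = np.arange(-n_lag, n_lag + 1) / fs
    return ComplexCorrelogram(
        lags_s=lags, values=values, normalization_N=N, rate_hz=fs
    )


def smooth_envelope(
    c: ComplexCorrelogram, len_samples: int = SMOOTHING_LEN
) -> ComplexCorrelogram:
    """Moving-average the correlation envelope |C|; complex values untouched."""
    if len_samples % 2 == 0:
        raise ValueError("smoothing window must be odd")
    return replace(
        c,
        smoothed_amplitude=moving_average(np.abs(c.values), len_samples),
        smoothing_len=len_samples,
    )


def noise_floor(
    c: ComplexCorrelogram,
    inner_s: float = NOISE_WINDOW_S[0],
    outer_s: float = NOISE_WINDOW_S[1],
) -> float:
    """95th percentile of the envelope over lags +-(inner, outer).

    Uses the smoothed envelope when present, so the floor sees the same
    processing as the signal region; falls back to the raw amplitude for
    unsmoothed correlograms.
    """
    eps = 0.5 / c.rate_hz
    if c.lags_s[0] > -(outer_s - eps) or c.lags_s[-1] < outer_s - eps:
        raise ValueError("lag axis does not cover the noise estimation windows")
    amp = c.smoothed_amplitude if c.smoothed_amplitude is not None else c.amplitude
    sel = (np.abs(c.lags_s) >= inner_s - eps) & (np.abs(c.lags_s) <= outer_s + eps)
    return float(np.percentile(amp[sel], 95))


def find_peak(
    c: ComplexCorrelogram,
    floor: float,
    window_s: tuple[float, float] = PEAK_WINDOW_S,
) -> DPOAEResult:
    """Peak of the smoothed envelope in the emission search window.

    Latency is the argmax lag (earliest on ties); phase is read from the
    unsmoothed complex correlation at that lag.  An insignificant result is
    returned, not raised.
    """
    if c.smoothed_amplitude is None:
        raise ValueError("correlogram must be smoothed before peak picking")
    eps = 0.5 / c.rate_hz
    sel = np.flatnonzero(
        (c.lags_s >= window_s[0] - eps) & (c.lags_s <= window_s[1] + eps)
    )
    if sel.size == 0:
        raise ValueError("lag axis does not cover the peak search window")
    amp = c.smoothed_amplitude[sel]
    i = sel[int(np.argmax(amp))]  # argmax returns the first (earliest) maximum
    peak = float(c.smoothed_amplitude[i])
    return DPOAEResult(
        peak_amplitude=peak,
        latency_s=float(c.lags_s[i]),
        phase_rad=float(np.angle(c.values[i])),
        noise_floor=float(floor),
        significant=bool(peak > floor),
        search_window_s=window_s,
    )


def estimate_equipment_delay(
    rec: MicRecording,
    eliciting: tuple[HarmonicWaveform, HarmonicWaveform],
    max_lag_s: float = 0.05,
    presence_threshold: float = 0.1,
    warn_difference_s: float = 0.5e-3,
) -> float:
    """Probe/system delay from the eliciting waveforms in the recording.

    Each eliciting waveform is cross-correlated with the recording; the lag
    of its envelope maximum is that waveform's delay, and the equipment delay
    is the mean of the two.  The stimuli dominate the recording, so a genuine
    peak has a normalized amplitude of order one; a peak below
    ``presence_threshold`` means the stimuli are absent.  A warning is issued
    when the two delays disagree by more than 0.5 ms.
    """
    delays = []
    for w in eliciting:
        c = complex_xcorr(rec, w, max_lag_s)
        amp = c.amplitude
        peak = float(amp.max())
        if peak < presence_threshold:
            raise ValueError("eliciting stimuli not found in recording")
        delays.append(float(c.lags_s[int(np.argmax(amp))]))
    if abs(delays[0] - delays[1]) > warn_difference_s:
        warnings.warn(
            f"eliciting-waveform delays disagree: {delays[0] * 1e3:.2f} ms vs "
            f"{delays[1] * 1e3:.2f} ms",
            stacklevel=2,
        )
    return float(np.mean(delays))


def preprocess(
    rec: MicRecording, trim_s: float = 3.0, delay_s: float = 0.0
) -> MicRecording:
    """Trim recording edges and compensate the equipment delay.

    The first and last ``trim_s`` seconds are removed (transient activity);
    the content is then shifted ``delay_s`` earlier so that the equipment
    delay subsequently reads as zero.  The delay must not exceed the trim.
    """
    fs = rec.rate_hz
    n_trim = int(round(trim_s * fs))
    n_delay = int(round(delay_s * fs))
    n = rec.samples.size
    if n <= 2 * n_trim:
        raise ValueError("recording shorter than twice the trim length")
    start, stop = n_trim + n_delay, n - n_trim + n_delay
    if start < 0 or stop > n:
        raise ValueError("delay compensation exceeds the trimmed margin")
    return MicRecording(
        samples=np.array(rec.samples[start:stop]),
        rate_hz=fs,
        equipment_delay_s=delay_s,
        trim_applied_s=trim_s,
    )
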