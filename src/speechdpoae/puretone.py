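"""Conventional pure-tone DPOAE analysis.

Two primaries f1 < f2 (defaults 1 and 1.2 kHz) elicit cubic distortion at
2*f1 - f2 and 2*f2 - f1.  The emission is quantified two ways: from the
power spectrum of the recording (noise = 95th percentile of the spectral
amplitudes 30-70 Hz to each side of the distortion frequency), and with the
same complex cross-correlation used for speech-derived emissions, against a
sinusoid at the lower-sideband frequency, with the noise level obtained by
repeating the procedure at an unrelated nearby frequency (default 900 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram

from .detection import complex_xcorr, find_peak, smooth_envelope
from .signals import HarmonicWaveform, MicRecording

__all__ = [
    "PureToneConfig",
    "PureToneDPOAEResult",
    "dp_frequencies",
    "synth_primaries",
    "spectrum_analysis",
    "xcorr_analysis",
]


@dataclass
class PureToneConfig:
    f1_hz: float = 1000.0
    f2_hz: float = 1200.0
    duration_s: float = 30.0
    level_rel: float = 0.5  # digital amplitude per primary (full scale)

    def __post_init__(self) -> None:
        if not self.f1_hz < self.f2_hz:
            raise ValueError("require f1 < f2")


@dataclass
class PureToneDPOAEResult:
    dp_freq_hz: float
    spectral_level: float | None = None
    noise_level: float | None = None
    significant: bool | None = None
    xcorr_amplitude: float | None = None
    xcorr_latency_s: float | None = None


def dp_frequencies(cfg: PureToneConfig) -> tuple[float, float]:
    """Cubic distortion-product frequencies (2*f1 - f2, 2*f2 - f1)."""
    lower = 2 * cfg.f1_hz - cfg.f2_hz
    upper = 2 * cfg.f2_hz - cfg.f1_hz
    if lower <= 0:
        raise ValueError("lower sideband 2*f1 - f2 is non-positive")
    return lower, upper


def synth_primaries(
    cfg: PureToneConfig, rate_hz: float = 44100.0
) -> tuple[HarmonicWaveform, HarmonicWaveform]:
    """The two primary tones as template-compatible waveforms."""
    n = int(round(cfg.duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    tones = []
    for f in (cfg.f1_hz, cfg.f2_hz):
        if f >= rate_hz / 2:
            raise ValueError("primary frequency beyond Nyquist")
        tones.append(
            HarmonicWaveform(
                samples=cfg.level_rel * np.cos(2 * np.pi * f * t),
                harmonic_n=1,
                rate_hz=rate_hz,
                source_id=f"puretone_{f:g}Hz",
            )
        )
    return tones[0], tones[1]


def _flank_noise(freqs: np.ndarray, amp: np.ndarray, f_dp: float) -> float:
    sel = (
        ((freqs >= f_dp - 70) & (freqs <= f_dp - 30))
        | ((freqs >= f_dp + 30) & (freqs <= f_dp + 70))
    )
    if not sel.any():
        raise ValueError("no spectral bins in the noise flanks")
    return float(np.percentile(amp[sel], 95))


def spectrum_analysis(
    rec: MicRecording, cfg: PureToneConfig
) -> tuple[PureToneDPOAEResult, PureToneDPOAEResult]:
    """Power-spectrum DPOAE levels and significance for both sidebands.

    A single full-length Hann periodogram; the distortion level is the
    spectral amplitude at the bin nearest the distortion frequency, the noise
    the 95th percentile of the amplitudes in the 30-70 Hz flanks on each
    side, pooled.
    """
    if rec.duration_s < 1.0:
        raise ValueError("recording shorter than 1 s")
    freqs, pxx = periodogram(rec.samples, fs=rec.rate_hz, window="hann")
    df = freqs[1] - freqs[0]
    if df > 10.0:
        raise ValueError("frequency resolution coarser than 10 Hz")
    amp = np.sqrt(pxx)
    results = []
    for f_dp in dp_frequencies(cfg):
        level = float(amp[int(np.argmin(np.abs(freqs - f_dp)))])
        noise = _flank_noise(freqs, amp, f_dp)
        results.append(
            PureToneDPOAEResult(
                dp_freq_hz=f_dp,
                spectral_level=level,
                noise_level=noise,
                significant=bool(level > noise),
            )
        )
    return results[0], results[1]


def xcorr_analysis(
    rec: MicRecording,
    cfg: PureToneConfig,
    noise_ref_hz: float = 900.0,
    smoothing_len: int = 199,
    max_lag_s: float = 0.75,
) -> PureToneDPOAEResult:
    """Cross-correlation analysis of the lower-sideband pure-tone DPOAE.

    The recording is correlated with a sinusoid at 2*f1 - f2; the envelope is
    smoothed and its peak in 0-7 ms taken.  The noise level is the 95th
    percentile of the smoothed envelope obtained by the same procedure at
    ``noise_ref_hz``, a frequency unrelated to the primaries and distortion
    products.
    """
    f_lower, f_upper = dp_frequencies(cfg)
    for f in (cfg.f1_hz, cfg.f2_hz, f_lower, f_upper):
        if abs(noise_ref_hz - f) < 25.0:
            raise ValueError(
                "noise reference frequency coincides with a primary or "
                "distortion-product frequency"
            )
    n = rec.samples.size
    t = np.arange(n) / rec.rate_hz

    def _smoothed(freq: float):
        tmpl = HarmonicWaveform(
            samples=np.cos(2 * np.pi * freq * t), harmonic_n=1, rate_hz=rec.rate_hz
        )
        return smooth_envelope(complex_xcorr(rec, tmpl, max_lag_s), smoothing_len)

    c_dp = _smoothed(f_lower)
    c_ref = _smoothed(noise_ref_hz)
    noise = float(np.percentile(c_ref.smoothed_amplitude, 95))
    peak = find_peak(c_dp, noise)
    return PureToneDPOAEResult(
        dp_freq_hz=f_lower,
        noise_level=noise,
        significant=peak.significant,
        xcorr_amplitude=peak.peak_amplitude,
        xcorr_latency_s=peak.latency_s,
    )
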