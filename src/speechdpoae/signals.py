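"""Waveform and pitch containers shared across the pipeline.

All audio is mono, dimensionless full-scale amplitude.  Pitch tracks carry a
per-frame fundamental frequency with voicing flags; the fundamental waveform
w0(t) is the speech bandpass-filtered around the mean fundamental, exactly
zero on unvoiced stretches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

F0_FLOOR_HZ = 40.0
F0_CEIL_HZ = 400.0


def _as_mono(samples) -> np.ndarray:
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a mono (1-D) sample array")
    return x


@dataclass
class SpeechSignal:
    """A mono speech recording at a given sampling rate."""

    samples: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.samples = _as_mono(self.samples)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class PitchTrack:
    """Frame-wise fundamental frequency f0(t) with voicing flags.

    ``f0_hz`` is NaN exactly where ``voiced`` is False.  Mean and SD are
    computed over voiced frames only (sample SD).
    """

    times_s: np.ndarray
    f0_hz: np.ndarray
    voiced: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.f0_hz = np.asarray(self.f0_hz, dtype=float)
        self.voiced = np.asarray(self.voiced, dtype=bool)
        if not (self.times_s.shape == self.f0_hz.shape == self.voiced.shape):
            raise ValueError("times_s, f0_hz and voiced must have equal shapes")
        if self.times_s.size and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("frame times must be strictly increasing")
        # enforce the defined-iff-voiced invariant
        self.f0_hz = np.where(self.voiced, self.f0_hz, np.nan)
        if np.any(~np.isfinite(self.f0_hz[self.voiced])):
            raise ValueError("voiced frames must carry a finite f0")
        f0v = self.f0_hz[self.voiced]
        if f0v.size and (f0v.min() < F0_FLOOR_HZ or f0v.max() > F0_CEIL_HZ):
            raise ValueError(
                f"voiced f0 must lie within [{F0_FLOOR_HZ}, {F0_CEIL_HZ}] Hz"
            )

    @property
    def n_voiced(self) -> int:
        return int(self.voiced.sum())

    @property
    def mean_f0_hz(self) -> float:
        if self.n_voiced == 0:
            raise ValueError("no voiced frames")
        return float(np.mean(self.f0_hz[self.voiced]))

    @property
    def sd_f0_hz(self) -> float:
        if self.n_voiced == 0:
            raise ValueError("no voiced frames")
        if self.n_voiced == 1:
            return 0.0
        return float(np.std(self.f0_hz[self.voiced], ddof=1))

    def sample_voiced_mask(self, rate_hz: float, n_samples: int) -> np.ndarray:
        """Nearest-frame voicing decision for every audio sample."""
        t = np.arange(n_samples) / rate_hz
        if self.times_s.size == 0:
            return np.zeros(n_samples, dtype=bool)
        midpoints = 0.5 * (self.times_s[:-1] + self.times_s[1:])
        idx = np.searchsorted(midpoints, t)
        return self.voiced[idx]

    def sample_f0(self, rate_hz: float, n_samples: int) -> np.ndarray:
        """Sample-wise f0, linearly interpolated within voiced stretches only.

        Unvoiced samples are NaN; interpolation never bridges unvoiced gaps.
        """
        t = np.arange(n_samples) / rate_hz
        out = np.full(n_samples, np.nan)
        mask = self.sample_voiced_mask(rate_hz, n_samples)
        from ._dsp import voiced_runs  # local import to avoid a cycle

        frame_voiced = np.flatnonzero(self.voiced)
        if frame_voiced.size == 0:
            return out
        tv = self.times_s[frame_voiced]
        fv = self.f0_hz[frame_voiced]
        for start, stop in voiced_runs(mask):
            out[start:stop] = np.interp(t[start:stop], tv, fv)
        return out


@dataclass
class FundamentalWaveform:
    """w0(t): the speech filtered around f0, gated to zero when unvoiced."""

    samples: np.ndarray
    rate_hz: float
    passband_hz: tuple[float, float]
    voiced_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = _as_mono(self.samples)
        if self.voiced_mask is not None:
            self.voiced_mask = np.asarray(self.voiced_mask, dtype=bool)
            if self.voiced_mask.shape != self.samples.shape:
                raise ValueError("voiced_mask must match the sample array")


@dataclass
class AnalyticWaveform:
    """Complex W0(t) = w0(t) + i*H[w0(t)]."""

    values: np.ndarray
    rate_hz: float


@dataclass
class HarmonicWaveform:
    """wn(t): envelope of w0 with the instantaneous phase multiplied by n."""

    samples: np.ndarray
    harmonic_n: int
    rate_hz: float
    source_id: str | None = None
    passband_hz: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.samples = _as_mono(self.samples)
        if self.harmonic_n < 1:
            raise ValueError("harmonic_n must be a positive integer")


@dataclass
class MicRecording:
    """Ear-canal microphone pressure signal r(t) plus preprocessing state."""

    samples: np.ndarray
    rate_hz: float
    equipment_delay_s: float | None = None
    trim_applied_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = _as_mono(self.samples)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    def __len__(self) -> int:
        return self.samples.size
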