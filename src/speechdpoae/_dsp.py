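"""Shared DSP primitives: analytic signals, voicing gates, instantaneous frequency."""

from __future__ import annotations

import numpy as np
from scipy.fft import fft, ifft, next_fast_len
from scipy.ndimage import uniform_filter1d


def analytic_signal(x: np.ndarray) -> np.ndarray:
    """Analytic representation ``x + i*H[x]`` via the one-sided spectrum method.

    The FFT length is padded to the next fast size; the result is truncated
    back, so only samples near the segment edges carry transform artifacts.
    The real part is returned as the input itself (the one-sided construction
    preserves it exactly; reusing the input avoids round-trip rounding).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("analytic_signal expects a non-empty 1-D array")
    n = x.size
    nfft = next_fast_len(n)
    spec = fft(x, nfft)
    weight = np.zeros(nfft)
    weight[0] = 1.0
    if nfft % 2 == 0:
        weight[nfft // 2] = 1.0
        weight[1 : nfft // 2] = 2.0
    else:
        weight[1 : (nfft + 1) // 2] = 2.0
    return x + 1j * np.imag(ifft(spec * weight)[:n])


def hilbert_transform(x: np.ndarray) -> np.ndarray:
    """Imaginary part of the analytic signal."""
    return np.imag(analytic_signal(x))


def voiced_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as half-open (start, stop) pairs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[mask[edges + 1]] + 1)
    stops = list(edges[~mask[edges + 1]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def raised_cosine_gate(mask: np.ndarray, rate_hz: float, ramp_s: float = 0.005) -> np.ndarray:
    """Gate that is 1 inside voiced runs, 0 outside, with raised-cosine ramps.

    Ramps live entirely inside each run, so every sample outside a run is
    exactly zero.  Runs shorter than two ramps get proportionally shortened
    ramps.
    """
    mask = np.asarray(mask, dtype=bool)
    gate = np.zeros(mask.size)
    n_ramp_full = int(round(ramp_s * rate_hz))
    for start, stop in voiced_runs(mask):
        length = stop - start
        gate[start:stop] = 1.0
        n_ramp = min(n_ramp_full, length // 2)
        if n_ramp > 0:
            ramp = np.sin(0.5 * np.pi * np.arange(1, n_ramp + 1) / n_ramp) ** 2
            gate[start : start + n_ramp] = ramp
            gate[stop - n_ramp : stop] = ramp[::-1]
    return gate


def instantaneous_frequency(x: np.ndarray, rate_hz: float) -> np.ndarray:
    """Phase-derivative frequency estimate (Hz) from the analytic signal."""
    phase = np.unwrap(np.angle(analytic_signal(x)))
    return np.gradient(phase) * rate_hz / (2.0 * np.pi)


def moving_average(x: np.ndarray, size: int) -> np.ndarray:
    """Centered moving average with reflect padding; ``size`` must be odd."""
    if size < 1 or size % 2 == 0:
        raise ValueError("moving-average window must be a positive odd integer")
    return uniform_filter1d(np.asarray(x, dtype=float), size=size, mode="reflect")


def edge_taper(x: np.ndarray, rate_hz: float, ramp_s: float = 0.02) -> np.ndarray:
    """Raised-cosine fade-in/out at the ends of a signal (returns a copy).

    Cutting a waveform mid-oscillation leaves a step edge whose spectral
    sidelobes correlate with nearby narrowband signals; tapering the cut
    restores the sidelobe suppression of the original voicing ramps.
    """
    y = np.array(x, dtype=float)
    n_ramp = min(int(round(ramp_s * rate_hz)), y.size // 2)
    if n_ramp > 0:
        ramp = np.sin(0.5 * np.pi * np.arange(1, n_ramp + 1) / n_ramp) ** 2
        y[:n_ramp] *= ramp
        y[y.size - n_ramp :] *= ramp[::-1]
    return y


def delay_samples(x: np.ndarray, n: int) -> np.ndarray:
    """Shift a signal ``n`` samples later (zero-fill at the head), same length."""
    if n < 0:
        raise ValueError("delay must be non-negative")
    if n == 0:
        return np.array(x, dtype=float)
    out = np.zeros_like(np.asarray(x, dtype=float))
    out[n:] = x[: x.size - n]
    return out
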