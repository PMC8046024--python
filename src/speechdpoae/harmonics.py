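"""Harmonic waveform synthesis by analytic-signal frequency shifting.

Given the fundamental waveform w0(t), its analytic representation is

    W0(t) = w0(t) + i*H[w0(t)],

and the waveform tracking the n-th harmonic of the fundamental is

    wn(t) = |W0(t)| * cos(n * arg W0(t)),

which preserves the amplitude envelope while multiplying the instantaneous
frequency by n.  Two such waveforms wm and wn (m < n) elicit cubic
distortion at the instantaneous frequencies (2m-n)*f0(t) (lower sideband)
and (2n-m)*f0(t) (upper sideband).
"""

from __future__ import annotations

import numpy as np

from ._dsp import analytic_signal, voiced_runs
from .signals import AnalyticWaveform, FundamentalWaveform, HarmonicWaveform

__all__ = ["analytic", "harmonic", "distortion_template"]


def analytic(w0: FundamentalWaveform) -> AnalyticWaveform:
    """Analytic representation of the fundamental waveform.

    When the waveform carries a voicing mask, the Hilbert transform is
    evaluated independently on each voiced stretch so that phase does not
    leak across silent gaps; unvoiced samples stay exactly zero.
    """
    x = w0.samples
    if x.size == 0:
        raise ValueError("empty fundamental waveform")
    if w0.voiced_mask is None:
        return AnalyticWaveform(values=analytic_signal(x), rate_hz=w0.rate_hz)
    values = np.zeros(x.size, dtype=complex)
    for start, stop in voiced_runs(w0.voiced_mask):
        values[start:stop] = analytic_signal(x[start:stop])
    return AnalyticWaveform(values=values, rate_hz=w0.rate_hz)


def harmonic(w0: FundamentalWaveform, n: int) -> HarmonicWaveform:
    """Waveform whose instantaneous frequency is n-fold the fundamental's.

    ``n = 1`` reproduces w0 exactly (the real part of its analytic signal).
    Raises if the shifted passband would alias (n * passband_high beyond
    Nyquist).
    """
    if n < 1:
        raise ValueError("harmonic index must be >= 1")
    if w0.passband_hz is not None and n * w0.passband_hz[1] >= w0.rate_hz / 2:
        raise ValueError(
            f"harmonic {n} of passband {w0.passband_hz} exceeds Nyquist "
            f"({w0.rate_hz / 2:g} Hz)"
        )
    W = analytic(w0).values
    if n == 1:
        samples = np.array(w0.samples, dtype=float)
    else:
        samples = np.abs(W) * np.cos(np.angle(W) * n)
        if w0.voiced_mask is not None:
            samples[~w0.voiced_mask] = 0.0
    passband = (
        (n * w0.passband_hz[0], n * w0.passband_hz[1])
        if w0.passband_hz is not None
        else None
    )
    return HarmonicWaveform(
        samples=samples, harmonic_n=n, rate_hz=w0.rate_hz, passband_hz=passband
    )


def distortion_template(
    m: int, n: int, w0: FundamentalWaveform, sideband: str = "lower"
) -> HarmonicWaveform:
    """Template for the cubic distortion of the eliciting pair (m, n).

    The lower sideband lives at harmonic 2m-n, the upper at 2n-m; for the
    9/11 pair those are the 7th and 13th harmonics, for the 6/8 pair the
    4th and 10th.
    """
    if not m < n:
        raise ValueError("require m < n for the eliciting pair")
    if sideband == "lower":
        k = 2 * m - n
        if k < 1:
            raise ValueError(f"lower sideband 2m-n = {k} is not a valid harmonic")
    elif sideband == "upper":
        k = 2 * n - m
    else:
        raise ValueError("sideband must be 'lower' or 'upper'")
    return harmonic(w0, k)
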