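"""Attentional modulation of emission amplitudes and its inference.

The relative attentional modulation of a paired measurement is the amplitude
difference divided by the average amplitude,

    A = 2 * (r_attended - r_ignored) / (r_attended + r_ignored),

computed per stimulus segment and averaged per subject.  Subject-level
significance uses one-sided t tests on per-interval modulation coefficients
(each 2-min segment split into 10 consecutive intervals, amplitudes read at
the segment-level peak latency).  Group-level inference is non-parametric: a
two-tailed one-sample Wilcoxon signed-rank test plus a 10,000-resample
bootstrap of the mean (percentile CI; one-sided p = fraction of resampled
means at or below zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._dsp import edge_taper
from .detection import complex_xcorr, smooth_envelope
from .signals import HarmonicWaveform, MicRecording

__all__ = [
    "PairedAmplitudes",
    "ModulationResult",
    "BootstrapResult",
    "modulation",
    "subject_modulation",
    "interval_modulations",
    "subject_test",
    "bootstrap_mean",
    "db_of_modulation",
    "group_tests",
]


@dataclass
class PairedAmplitudes:
    """Peak amplitudes of one segment measured attended and ignored."""

    r_attended: float
    r_ignored: float
    voice: str = "male"
    segment_id: str = ""
    latency_attended_s: float | None = None
    latency_ignored_s: float | None = None

    def __post_init__(self) -> None:
        if self.r_attended < 0 or self.r_ignored < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass
class ModulationResult:
    A: float
    per_segment_A: list[float]
    per_interval_A: list[float] = field(default_factory=list)
    subject_p: float | None = None
    latency_diff_s: float | None = None


@dataclass
class BootstrapResult:
    mean_estimate: float
    ci95: tuple[float, float]
    p_one_sided: float
    n_resamples: int
    seed: int


def modulation(pair: PairedAmplitudes) -> float:
    """A = 2*(rA - rI)/(rA + rI): antisymmetric, bounded in (-2, 2)."""
    rA, rI = pair.r_attended, pair.r_ignored
    if rA + rI <= 0:
        raise ValueError("both amplitudes are zero: modulation undefined")
    return 2.0 * (rA - rI) / (rA + rI)


def subject_modulation(pairs: list[PairedAmplitudes]) -> ModulationResult:
    """Mean per-segment modulation (and latency difference) for one subject."""
    if not pairs:
        raise ValueError("need at least one pair")
    voices = {p.voice for p in pairs}
    if len(voices) > 1:
        raise ValueError(f"mixed voices in one subject call: {sorted(voices)}")
    per_segment = [modulation(p) for p in pairs]
    lat_diffs = [
        p.latency_attended_s - p.latency_ignored_s
        for p in pairs
        if p.latency_attended_s is not None and p.latency_ignored_s is not None
    ]
    return ModulationResult(
        A=float(np.mean(per_segment)),
        per_segment_A=per_segment,
        latency_diff_s=float(np.mean(lat_diffs)) if lat_diffs else None,
    )


def interval_modulations(
    rec_attended: MicRecording,
    rec_ignored: MicRecording,
    template: HarmonicWaveform,
    segment_latency_s: float,
    k: int = 10,
    smoothing_len: int = 199,
    max_lag_s: float = 0.02,
) -> list[float]:
    """Per-interval modulation coefficients for one segment pair.

    Both recordings (and the time-locked template) are split into ``k``
    consecutive equal intervals; in each interval the smoothed correlation
    amplitude is read at the fixed segment-level peak latency, and the paired
    coefficients A are returned.  Each interval's template is edge-tapered
    (20-ms raised cosine) so that cutting a voiced stretch at an interval
    boundary does not bleed stimulus energy into the correlation.
    """
    if k < 2:
        raise ValueError("need at least two intervals")
    if rec_attended.samples.size != rec_ignored.samples.size:
        raise ValueError("recordings must have equal duration")
    if rec_attended.rate_hz != rec_ignored.rate_hz:
        raise ValueError("recordings must share the sampling rate")
    n = min(rec_attended.samples.size, template.samples.size)
    n_int = n // k
    if n_int < rec_attended.rate_hz:  # < 1 s
        raise ValueError("intervals shorter than 1 s")

    def _amplitude(rec: MicRecording, start: int, stop: int) -> float:
        sub_rec = MicRecording(rec.samples[start:stop], rec.rate_hz)
        sub_tmpl = HarmonicWaveform(
            samples=edge_taper(template.samples[start:stop], template.rate_hz),
            harmonic_n=template.harmonic_n,
            rate_hz=template.rate_hz,
        )
        c = smooth_envelope(complex_xcorr(sub_rec, sub_tmpl, max_lag_s), smoothing_len)
        idx = int(np.argmin(np.abs(c.lags_s - segment_latency_s)))
        return float(c.smoothed_amplitude[idx])

    coeffs = []
    for j in range(k):
        start, stop = j * n_int, (j + 1) * n_int
        pair = PairedAmplitudes(
            r_attended=_amplitude(rec_attended, start, stop),
            r_ignored=_amplitude(rec_ignored, start, stop),
        )
        coeffs.append(modulation(pair))
    return coeffs


def subject_test(per_interval_A: list[float]) -> float:
    """One-sided one-sample t test of the interval coefficients against 0."""
    values = np.asarray(per_interval_A, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two coefficients")
    if np.std(values, ddof=1) == 0.0:
        raise ValueError("degenerate sample: zero variance")
    return float(stats.ttest_1samp(values, 0.0, alternative="greater").pvalue)


def bootstrap_mean(
    values: list[float], n_resamples: int = 10000, seed: int = 0
) -> BootstrapResult:
    """Bootstrap of the sample mean: percentile 95% CI and one-sided p.

    ``p_one_sided`` is the fraction of resampled means that are <= 0, i.e.
    the bootstrap evidence against a positive population mean.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_resamples, x.size))
    means = x[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return BootstrapResult(
        mean_estimate=float(means.mean()),
        ci95=(float(lo), float(hi)),
        p_one_sided=float(np.mean(means <= 0.0)),
        n_resamples=n_resamples,
        seed=seed,
    )


def db_of_modulation(A: float) -> float:
    """Express a relative modulation as a decibel change, 20*log10(1 + A)."""
    if A <= -1.0:
        raise ValueError("modulation <= -1 has no decibel representation")
    return float(20.0 * np.log10(1.0 + A))


def _iqr_outlier_mask(x: np.ndarray) -> np.ndarray:
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return (x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)


def group_tests(subject_values: list[float], rerun_without_outliers: bool = True) -> dict:
    """Two-tailed one-sample Wilcoxon signed-rank test across subjects.

    Optionally reruns after removing 1.5*IQR outliers.  Raises for fewer
    than five subjects or an all-tied sample.
    """
    x = np.asarray(subject_values, dtype=float)
    if x.size < 5:
        raise ValueError("need at least five subjects for the group test")
    if np.all(x == x[0]):
        raise ValueError("all subject values tied")
    report: dict = {"n": int(x.size)}
    report["wilcoxon_p"] = float(stats.wilcoxon(x, alternative="two-sided").pvalue)
    if rerun_without_outliers:
        mask = _iqr_outlier_mask(x)
        kept = x[~mask]
        report["n_outliers_removed"] = int(mask.sum())
        if mask.any() and kept.size >= 5 and not np.all(kept == kept[0]):
            report["wilcoxon_p_without_outliers"] = float(
                stats.wilcoxon(kept, alternative="two-sided").pvalue
            )
        else:
            report["wilcoxon_p_without_outliers"] = report["wilcoxon_p"]
    return report
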