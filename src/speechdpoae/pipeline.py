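"""End-to-end pipelines: emission detection from files and attention reports.

``run_detect`` composes the full measurement chain — pitch, fundamental
waveform, harmonic templates, equipment-delay compensation, trimming,
complex cross-correlation, envelope smoothing, noise floor, peak — and
writes the results TSV plus a correlogram dump, each accompanied by the
fully resolved configuration.  ``run_attention`` turns a subject table of
paired peak amplitudes into per-subject modulations and group statistics.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sdio
from ._dsp import edge_taper
from .attention import PairedAmplitudes, bootstrap_mean, group_tests, subject_modulation
from .detection import (
    complex_xcorr,
    estimate_equipment_delay,
    find_peak,
    noise_floor,
    preprocess,
    smooth_envelope,
)
from .harmonics import distortion_template, harmonic
from .pitch import estimate_pitch, extract_fundamental, load_pitch_track
from .signals import HarmonicWaveform, MicRecording, SpeechSignal

logger = logging.getLogger("speechdpoae")

HARMONIC_PAIRS = {"male": (9, 11), "female": (6, 8)}


@dataclass
class RunConfig:
    """Resolved pipeline parameters; defaults are the standard measurement protocol."""

    rate_hz: float = 44100.0
    harmonic_pairs: dict = field(default_factory=lambda: dict(HARMONIC_PAIRS))
    trim_s: float = 3.0
    smoothing_len: int = 199
    noise_window_s: tuple[float, float] = (0.070, 0.750)
    peak_window_s: tuple[float, float] = (0.0, 0.007)
    bootstrap_n: int = 10000
    seed: int = 0
    pitch_frame_s: float = 0.040
    pitch_hop_s: float = 0.010
    pitch_search_hz: tuple[float, float] = (40.0, 400.0)
    voicing_threshold: float = 0.45
    require_significant: bool = True
    exclude_subjects: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["harmonic_pairs"] = {k: list(v) for k, v in d["harmonic_pairs"].items()}
        return d

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        import json

        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        if "harmonic_pairs" in raw:
            raw["harmonic_pairs"] = {
                k: tuple(v) for k, v in raw["harmonic_pairs"].items()
            }
        for key in ("noise_window_s", "peak_window_s", "pitch_search_hz", "exclude_subjects"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _trim_template(t: HarmonicWaveform, trim_s: float) -> HarmonicWaveform:
    n_trim = int(round(trim_s * t.rate_hz))
    stop = t.samples.size - n_trim
    if stop <= n_trim:
        raise ValueError("template shorter than twice the trim length")
    return HarmonicWaveform(
        samples=edge_taper(t.samples[n_trim:stop], t.rate_hz),
        harmonic_n=t.harmonic_n,
        rate_hz=t.rate_hz,
        source_id=t.source_id,
        passband_hz=t.passband_hz,
    )


def run_detect(
    stimulus_wav,
    recording_wav,
    pitch="auto",
    voice: str = "male",
    cfg: RunConfig | None = None,
    out_prefix: str | None = None,
):
    """Detect the speech-evoked emission for one stimulus/recording pair.

    ``pitch`` is a CSV path or ``"auto"`` to run the built-in tracker.
    Returns the detection result; with ``out_prefix`` also writes
    ``<prefix>.tsv``, ``<prefix>_correlogram.csv`` and ``<prefix>_config.json``.
    """
    cfg = cfg or RunConfig()
    if voice not in cfg.harmonic_pairs:
        raise ValueError(f"unknown voice {voice!r}")
    m, n = cfg.harmonic_pairs[voice]

    x, rate = sdio.read_wav(stimulus_wav, cfg.rate_hz)
    speech = SpeechSignal(samples=x, rate_hz=rate)
    if pitch is None or pitch == "auto":
        track = estimate_pitch(
            speech,
            frame_s=cfg.pitch_frame_s,
            hop_s=cfg.pitch_hop_s,
            search_hz=cfg.pitch_search_hz,
            voicing_threshold=cfg.voicing_threshold,
        )
    else:
        track = load_pitch_track(pitch)
    w0 = extract_fundamental(speech, track)
    logger.info("passband %.1f-%.1f Hz", *w0.passband_hz)

    eliciting = (harmonic(w0, m), harmonic(w0, n))
    template = distortion_template(m, n, w0, "lower")

    r, rrate = sdio.read_wav(recording_wav, cfg.rate_hz)
    rec = MicRecording(samples=r, rate_hz=rrate)
    try:
        delay = estimate_equipment_delay(rec, eliciting)
    except ValueError:
        warnings.warn(
            "eliciting stimuli not found in recording; assuming zero equipment delay",
            stacklevel=2,
        )
        delay = 0.0
    logger.info("equipment delay %.3f ms", delay * 1e3)

    rec = preprocess(rec, trim_s=cfg.trim_s, delay_s=delay)
    template = _trim_template(template, cfg.trim_s)
    c = smooth_envelope(
        complex_xcorr(rec, template, cfg.noise_window_s[1]), cfg.smoothing_len
    )
    floor = noise_floor(c, *cfg.noise_window_s)
    result = find_peak(c, floor, cfg.peak_window_s)
    logger.info(
        "noise floor %.3g, peak %.3g at %.2f ms (significant=%s)",
        floor,
        result.peak_amplitude,
        result.latency_s * 1e3,
        result.significant,
    )

    if out_prefix is not None:
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        sdio.write_results_tsv(
            [sdio.result_row(str(recording_wav), result)], f"{prefix}.tsv"
        )
        sdio.write_correlogram_csv(c, f"{prefix}_correlogram.csv")
        sdio.write_json(
            {"config": cfg.to_dict(), "voice": voice, "equipment_delay_s": delay},
            f"{prefix}_config.json",
        )
    return result


REQUIRED_TABLE_COLUMNS = [
    "subject_id",
    "voice",
    "segment_id",
    "condition",
    "peak_amplitude",
    "latency_ms",
    "significant",
]


def run_attention(table, cfg: RunConfig | None = None, out_json=None) -> dict:
    """Attention report from a subject table of paired peak amplitudes.

    The table (TSV path or DataFrame) has one row per recording with columns
    ``subject_id, voice, segment_id, condition(attended|ignored),
    peak_amplitude, latency_ms, significant``.  Exclusion filters (explicit
    subject list; subjects with non-significant recordings for a voice) are
    applied per the configuration.
    """
    cfg = cfg or RunConfig()
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table, sep="\t")
    if df.empty:
        raise ValueError("empty subject table")
    missing = set(REQUIRED_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    bad = df[~df["condition"].isin(["attended", "ignored"])]
    if len(bad):
        raise ValueError(
            f"invalid condition values in rows {bad.index.tolist()}"
        )

    df = df[~df["subject_id"].astype(str).isin(cfg.exclude_subjects)]
    report: dict = {"config": cfg.to_dict(), "voices": {}, "excluded": {}}
    for voice, dvoice in df.groupby("voice"):
        subject_A: dict[str, float] = {}
        excluded = []
        for subject, dsub in dvoice.groupby("subject_id"):
            if cfg.require_significant and not dsub["significant"].astype(bool).all():
                excluded.append(str(subject))
                continue
            pairs = []
            for segment, dseg in dsub.groupby("segment_id"):
                att = dseg[dseg["condition"] == "attended"]
                ign = dseg[dseg["condition"] == "ignored"]
                if len(att) != 1 or len(ign) != 1:
                    raise ValueError(
                        f"segment {segment!r} of subject {subject!r} is not a "
                        "single attended/ignored pair"
                    )
                pairs.append(
                    PairedAmplitudes(
                        r_attended=float(att["peak_amplitude"].iloc[0]),
                        r_ignored=float(ign["peak_amplitude"].iloc[0]),
                        voice=str(voice),
                        segment_id=str(segment),
                        latency_attended_s=float(att["latency_ms"].iloc[0]) / 1e3,
                        latency_ignored_s=float(ign["latency_ms"].iloc[0]) / 1e3,
                    )
                )
            subject_A[str(subject)] = subject_modulation(pairs)
        values = [m.A for m in subject_A.values()]
        voice_report = {
            "n_subjects": len(values),
            "subject_modulation": {s: m.A for s, m in subject_A.items()},
            "subject_latency_diff_ms": {
                s: (None if m.latency_diff_s is None else m.latency_diff_s * 1e3)
                for s, m in subject_A.items()
            },
            "mean_modulation": float(np.mean(values)) if values else None,
        }
        if len(values) >= 5:
            voice_report["group"] = group_tests(values)
            boot = bootstrap_mean(values, n_resamples=cfg.bootstrap_n, seed=cfg.seed)
            voice_report["bootstrap"] = dataclasses.asdict(boot)
        else:
            warnings.warn(
                f"voice {voice!r}: fewer than five subjects, group tests skipped",
                stacklevel=2,
            )
        report["voices"][str(voice)] = voice_report
        report["excluded"][str(voice)] = excluded
    if out_json is not None:
        sdio.write_json(report, out_json)
    return report
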