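"""File I/O: WAV audio, pitch CSV, results TSV, correlogram CSV, JSON reports.

WAV files are read with :mod:`scipy.io.wavfile`; integer PCM (16/24/32-bit,
unsigned 8-bit) is rescaled to float full scale, multi-channel input is
rejected (the pipeline is mono end to end), and recordings at other rates are
polyphase-resampled on load when a target rate is given.  Float WAV is
preferred on write for bit round-trips.
"""

from __future__ import annotations

import dataclasses
import json
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

from .detection import ComplexCorrelogram, DPOAEResult

__all__ = [
    "read_wav",
    "write_wav",
    "write_results_tsv",
    "write_correlogram_csv",
    "write_json",
]

_INT_SCALES = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31}


def read_wav(path, target_rate_hz: float | None = None) -> tuple[np.ndarray, float]:
    """Read a mono WAV as float64 full scale; optionally resample."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("expected a mono WAV file")
    if data.dtype in _INT_SCALES:
        x = data.astype(float) / _INT_SCALES[data.dtype]
    elif data.dtype == np.dtype("uint8"):
        x = (data.astype(float) - 128.0) / 128.0
    else:
        x = data.astype(float)
    rate = float(rate)
    if target_rate_hz is not None and rate != target_rate_hz:
        frac = Fraction(target_rate_hz / rate).limit_denominator(1000)
        x = resample_poly(x, frac.numerator, frac.denominator)
        rate = float(target_rate_hz)
    return x, rate


def write_wav(path, samples: np.ndarray, rate_hz: float) -> None:
    wavfile.write(path, int(round(rate_hz)), np.asarray(samples, dtype=np.float32))


def write_results_tsv(rows: list[dict], path) -> None:
    """One row per recording: amplitude, latency, phase, floor, significance."""
    columns = [
        "recording",
        "peak_amplitude",
        "latency_ms",
        "phase_rad",
        "noise_floor",
        "significant",
    ]
    df = pd.DataFrame(rows)
    for c in columns:
        if c not in df.columns:
            df[c] = np.nan
    df[columns].to_csv(path, sep="\t", index=False)


def result_row(name: str, res: DPOAEResult) -> dict:
    return {
        "recording": name,
        "peak_amplitude": res.peak_amplitude,
        "latency_ms": res.latency_s * 1e3,
        "phase_rad": res.phase_rad,
        "noise_floor": res.noise_floor,
        "significant": res.significant,
    }


def write_correlogram_csv(c: ComplexCorrelogram, path) -> None:
    smoothed = (
        c.smoothed_amplitude
        if c.smoothed_amplitude is not None
        else np.full(c.values.size, np.nan)
    )
    pd.DataFrame(
        {
            "lag_ms": c.lags_s * 1e3,
            "re": c.values.real,
            "im": c.values.imag,
            "amp": np.abs(c.values),
            "amp_smoothed": smoothed,
        }
    ).to_csv(path, index=False)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(obj), fh, indent=2)
        fh.write("\n")
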