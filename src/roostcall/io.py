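"""Readers and writers for the pipeline's on-disk formats.

Audio travels as standard PCM WAV (16-bit written; 8/16/32-bit int and
float read, stereo downmixed).  Tabular artifacts are tidy CSV with
fixed column names; PSD series carry their metadata as '#'-prefixed
header lines above the two-column body.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .acoustic import AudioNight, PsdSeries
from .departures import DepartureEvent, DepartureSummary
from .metrics import NightMetrics

__all__ = [
    "read_wav",
    "write_wav",
    "write_psd_csv",
    "read_psd_csv",
    "read_events_csv",
    "write_events_csv",
    "write_metrics_csv",
    "read_metrics_csv",
    "write_summaries_csv",
    "write_json",
]

_PCM_SCALE = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31,
              np.dtype("uint8"): 2**7}


def read_wav(path: str | Path, site: str = "", date: str = "") -> AudioNight:
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.dtype in _PCM_SCALE:
        offset = 128 if data.dtype == np.dtype("uint8") else 0
        data = (data.astype(np.float64) - offset) / _PCM_SCALE[data.dtype]
    else:
        data = data.astype(np.float64)
    return AudioNight(samples=data, sample_rate=float(rate), site=site, date=date)


def write_wav(path: str | Path, audio: AudioNight) -> None:
    peak = np.max(np.abs(audio.samples)) if len(audio.samples) else 0.0
    samples = audio.samples / peak if peak > 1.0 else audio.samples
    pcm = np.clip(samples * (2**15 - 1), -(2**15), 2**15 - 1).astype(np.int16)
    wavfile.write(str(path), int(audio.sample_rate), pcm)


def write_psd_csv(path: str | Path, psd: PsdSeries) -> None:
    with open(path, "w") as fh:
        fh.write(f"# band_hz: {psd.band_hz[0]} {psd.band_hz[1]}\n")
        fh.write(f"# t0_s: {psd.t0_s}\n")
        fh.write(f"# normalized: {int(psd.normalized)}\n")
        fh.write("time_s,value\n")
        for t, v in zip(psd.times_s, psd.values):
            fh.write(f"{t:.1f},{v:.10g}\n")


def read_psd_csv(path: str | Path) -> PsdSeries:
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    values = [float(line.split(",")[1]) for line in lines[body_start + 1:] if line.strip()]
    band = tuple(float(x) for x in meta.get("band_hz", "0 0").split())
    return PsdSeries(
        values=np.asarray(values),
        t0_s=float(meta.get("t0_s", 0.0)),
        band_hz=band,  # type: ignore[arg-type]
        normalized=bool(int(meta.get("normalized", "0"))),
    )


def read_events_csv(path: str | Path) -> list[DepartureEvent]:
    df = pd.read_csv(path)
    required = {"time_s", "n_birds", "direction"}
    if not required <= set(df.columns):
        raise ValueError(f"events CSV needs columns {sorted(required)}")
    return [
        DepartureEvent(time_s=float(r.time_s), n_birds=int(r.n_birds),
                       direction=str(r.direction))
        for r in df.itertuples(index=False)
    ]


def write_events_csv(path: str | Path, events: list[DepartureEvent]) -> None:
    pd.DataFrame(
        [{"time_s": e.time_s, "n_birds": e.n_birds, "direction": e.direction}
         for e in events]
    ).to_csv(path, index=False)


def write_metrics_csv(path: str | Path, metrics: list[NightMetrics]) -> None:
    pd.DataFrame([m.to_row() for m in metrics]).to_csv(path, index=False)


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_summaries_csv(path: str | Path, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json(path: str | Path, payload: dict) -> None:
    def default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default)
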