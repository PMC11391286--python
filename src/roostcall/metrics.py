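"""Per-night response variables and background-noise covariates.

Three calling statistics summarize each night's nPSD series:

* **settling slope** — OLS slope of the first hour after arrival,
  in normalized dB Hz^-1 h^-1 (negative = birds quietening down);
* **night-calling proportion** — fraction of overnight seconds whose
  nPSD meets a threshold (0.2 default, 0.4 as a conservative check),
  a proxy for nocturnal disturbance;
* **pre-departure slope** — OLS slope of the final 1.5 h (positive =
  the calling crescendo that precedes a coordinated mass departure).

Background noise is quantified as mean normalized 0-4000 Hz band power
in three windows: the hour before arrival, two hours mid-night, and the
hour before continuous departure calling begins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .acoustic import (
    AudioNight,
    PsdSeries,
    band_psd_series,
    build_noise_profile,
    normalize_night,
    spectral_noise_reduce,
    trim_to_occupancy,
)
from .config import PipelineConfig

__all__ = [
    "NightMetrics",
    "settling_slope",
    "predeparture_slope",
    "night_calling_proportion",
    "detect_departure_calling_onset",
    "background_noise_levels",
    "assemble_night_metrics",
]


@dataclass(frozen=True)
class NightMetrics:
    """Derived statistics for one roost-night, joined with covariates."""

    site: str
    date: str
    month: str
    settle_slope: float
    night_call_prop: float
    night_call_prop_alt: float
    predeparture_slope: float
    noise_prearrival: float
    noise_overnight: float
    noise_predeparture: float
    roost_size: float = math.nan
    temp_mean: float = math.nan
    wind_mean: float = math.nan
    rain: float = math.nan
    light_mean: float = math.nan   # NaN where the light logger failed
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.night_call_prop <= 1.0:
            raise ValueError("night_call_prop must lie in [0, 1]")
        for name in ("settle_slope", "predeparture_slope"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def light_present(self) -> bool:
        return math.isfinite(self.light_mean)

    def to_row(self) -> dict:
        return {
            "site": self.site, "date": self.date, "month": self.month,
            "settle_slope": self.settle_slope,
            "night_call_prop": self.night_call_prop,
            "night_call_prop_alt": self.night_call_prop_alt,
            "predeparture_slope": self.predeparture_slope,
            "noise_prearrival": self.noise_prearrival,
            "noise_overnight": self.noise_overnight,
            "noise_predeparture": self.noise_predeparture,
            "roost_size": self.roost_size, "temp_mean": self.temp_mean,
            "wind_mean": self.wind_mean, "rain": self.rain,
            "light_mean": self.light_mean,
        }


def _ols_slope_per_hour(values: np.ndarray) -> float:
    """OLS slope of `values` against time in seconds, reported per hour."""
    t = np.arange(len(values), dtype=np.float64)
    t -= t.mean()
    denom = float(t @ t)
    if denom == 0.0:
        return 0.0
    return float(t @ (values - values.mean()) / denom) * 3600.0


def settling_slope(npsd: PsdSeries, window_s: int = 3600) -> float:
    """Post-arrival settling rate: OLS slope over the first `window_s`
    seconds of the normalized series, per hour.  Negative = settling;
    slightly positive slopes do occur and are retained."""
    if not npsd.normalized:
        raise ValueError("settling_slope expects a normalized series")
    if len(npsd) < window_s:
        raise ValueError(f"series of {len(npsd)} s shorter than window {window_s} s")
    return _ols_slope_per_hour(npsd.values[:window_s])


def predeparture_slope(npsd: PsdSeries, window_s: int = 5400) -> float:
    """Pre-departure crescendo rate: OLS slope over the final `window_s`
    seconds, per hour.  Positive = calling building toward departure."""
    if not npsd.normalized:
        raise ValueError("predeparture_slope expects a normalized series")
    if len(npsd) < window_s:
        raise ValueError(f"series of {len(npsd)} s shorter than window {window_s} s")
    return _ols_slope_per_hour(npsd.values[-window_s:])


def night_calling_proportion(
    npsd: PsdSeries,
    threshold: float = 0.2,
    settle_offset_s: int = 3600,
    predeparture_exclusion_s: int = 5400,
) -> float:
    """Fraction of overnight seconds at or above `threshold` nPSD.

    The window runs from `settle_offset_s` after the (trimmed) series
    start to `predeparture_exclusion_s` before its end — i.e. after the
    birds have settled until 1.5 h before departure.
    """
    if not npsd.normalized:
        raise ValueError("night_calling_proportion expects a normalized series")
    window = npsd.values[settle_offset_s: len(npsd) - predeparture_exclusion_s]
    if len(window) == 0:
        raise ValueError("overnight window is empty for this series")
    return float(np.mean(window >= threshold))


def detect_departure_calling_onset(
    npsd: PsdSeries,
    threshold: float = 0.2,
    run_s: int = 60,
    window_s: int = 5400,
) -> float:
    """Deterministic surrogate for the (visually identified) onset of
    continuous departure calling: the first second of the final
    `window_s` whose nPSD stays >= `threshold` for `run_s` consecutive
    seconds; falls back to the window start if no such run exists.
    Returns a time in seconds from the recording start."""
    if not npsd.normalized:
        raise ValueError("onset detection expects a normalized series")
    start = max(0, len(npsd) - window_s)
    tail = npsd.values[start:]
    above = tail >= threshold
    if run_s <= len(above):
        run = np.convolve(above.astype(int), np.ones(run_s, dtype=int), mode="valid")
        hits = np.nonzero(run == run_s)[0]
        if len(hits):
            return npsd.t0_s + start + float(hits[0])
    return npsd.t0_s + start


def background_noise_levels(
    raw_audio: AudioNight,
    arrival_anchor_s: float,
    departure_calling_onset_s: float,
    window_s: float = 3600.0,
    night_window_s: tuple[float, float] | None = None,
    profile_len_s: float = 300.0,
    band: tuple[float, float] = (0.0, 4000.0),
    reduction_db: float = 6.0,
) -> tuple[float, float, float]:
    """Mean normalized background-noise level in three windows.

    Windows: the `window_s` before the arrival anchor, a mid-night
    stretch (default the 23:00-01:00 portion of a 16:00-08:00 night,
    i.e. 43.75-56.25% of the recording), and the `window_s` before the
    onset of continuous departure calling.  A noise profile extracted
    from the calling-dense arrival period drives 6 dB noise reduction
    (suppressing residual calls); band power over 0-4000 Hz is then
    normalized jointly across the three windows and averaged per
    window.  Returns (prearrival, overnight, predeparture).
    """
    dur = raw_audio.duration_s
    if night_window_s is None:
        night_window_s = (0.4375 * dur, 0.5625 * dur)
    windows = [
        (arrival_anchor_s - window_s, arrival_anchor_s),
        night_window_s,
        (departure_calling_onset_s - window_s, departure_calling_onset_s),
    ]
    for t0, t1 in windows:
        if t0 < 0 or t1 > dur + 1e-9 or t1 <= t0:
            raise ValueError(f"noise window [{t0:.1f}, {t1:.1f}] outside recording")
    profile = build_noise_profile(
        raw_audio,
        (arrival_anchor_s, min(arrival_anchor_s + max(profile_len_s, 10.0), dur)),
    )
    series = []
    for t0, t1 in windows:
        seg = raw_audio.segment(t0, t1)
        reduced = spectral_noise_reduce(seg, profile, reduction_db)
        series.append(band_psd_series(reduced, band).values)
    pooled = np.concatenate(series)
    lo, hi = pooled.min(), pooled.max()
    if hi - lo == 0.0:
        return (0.0, 0.0, 0.0)
    means = [float(np.mean((v - lo) / (hi - lo))) for v in series]
    return (means[0], means[1], means[2])


def assemble_night_metrics(
    audio: AudioNight,
    covariates: dict | None = None,
    config: PipelineConfig | None = None,
) -> NightMetrics:
    """Run the full per-night chain and attach covariates.

    noise-reduce -> call-band PSD -> occupancy trim -> normalize ->
    {settling slope, night-calling proportion (both thresholds),
    pre-departure slope} + the three background-noise means.  Stage
    failures re-raise with the stage named.
    """
    cfg = config or PipelineConfig()
    cov = dict(covariates or {})
    dur = audio.duration_s

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

    t0 = cfg.noise_profile_start_frac * dur
    t1 = min(t0 + max(cfg.noise_profile_len_s, 10.0), dur)
    profile = stage("noise_profile", build_noise_profile, audio, (t0, t1))
    reduced = stage("noise_reduce", spectral_noise_reduce, audio, profile,
                    cfg.noise_reduction_db)
    psd = stage("band_psd", band_psd_series, reduced, cfg.band_call_hz)
    trimmed = stage("trim", trim_to_occupancy, psd, cfg.head_trim_s, cfg.tail_trim_s)
    npsd = stage("normalize", normalize_night, trimmed)

    settle = stage("settling_slope", settling_slope, npsd, cfg.settle_window_s)
    predep = stage("predeparture_slope", predeparture_slope, npsd,
                   cfg.predeparture_window_s)
    prop = stage("night_calling", night_calling_proportion, npsd,
                 cfg.call_threshold, cfg.settle_window_s, cfg.predeparture_window_s)
    prop_alt = stage("night_calling_alt", night_calling_proportion, npsd,
                     cfg.alt_threshold, cfg.settle_window_s, cfg.predeparture_window_s)

    run_s = max(5, cfg.predeparture_window_s // 90)
    onset = cov.pop("departure_calling_onset_s", None)
    if onset is None:
        onset = stage("onset_detection", detect_departure_calling_onset, npsd,
                      cfg.call_threshold, run_s, cfg.predeparture_window_s)
    arrival = cov.pop("arrival_anchor_s", npsd.t0_s)
    pre_w = min(float(cfg.noise_window_s), arrival) if arrival > 0 else 0.0
    if pre_w < 1.0 or onset < 1.0:
        noise = (math.nan, math.nan, math.nan)
    else:
        noise = stage(
            "background_noise", background_noise_levels, audio, arrival, onset,
            min(float(cfg.noise_window_s), arrival, onset),
            None, cfg.noise_profile_len_s, cfg.band_noise_hz,
            cfg.noise_reduction_db,
        )

    return NightMetrics(
        site=str(cov.pop("site", audio.site)),
        date=str(cov.pop("date", audio.date)),
        month=str(cov.pop("month", "")),
        settle_slope=settle,
        night_call_prop=prop,
        night_call_prop_alt=prop_alt,
        predeparture_slope=predep,
        noise_prearrival=noise[0],
        noise_overnight=noise[1],
        noise_predeparture=noise[2],
        roost_size=float(cov.pop("roost_size", math.nan)),
        temp_mean=float(cov.pop("temp_mean", math.nan)),
        wind_mean=float(cov.pop("wind_mean", math.nan)),
        rain=float(cov.pop("rain", math.nan)),
        light_mean=float(cov.pop("light_mean", math.nan)),
        extras=cov,
    )
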