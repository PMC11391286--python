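"""Per-night calling statistics and background-noise covariates."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roostcall import (
    NightScenario,
    PsdSeries,
    assemble_night_metrics,
    background_noise_levels,
    detect_departure_calling_onset,
    night_calling_proportion,
    predeparture_slope,
    settling_slope,
    simulate_night,
)
from roostcall.acoustic import band_psd_series, normalize_night, trim_to_occupancy


def series(values, normalized=True, t0=0.0):
    return PsdSeries(values=np.asarray(values, dtype=float), t0_s=t0,
                     band_hz=(1000, 3000), normalized=normalized)


def naive_slope_per_hour(values):
    """Textbook OLS slope vs seconds, scaled to per-hour — explicit
    loop oracle independent of the vectorized implementation."""
    n = len(values)
    tbar = sum(range(n)) / n
    vbar = sum(values) / n
    num = sum((t - tbar) * (v - vbar) for t, v in enumerate(values))
    den = sum((t - tbar) ** 2 for t in range(n))
    return num / den * 3600.0


class TestSlopes:
    def test_linear_decline_gives_minus_one_per_hour(self):
        values = 1.0 - np.arange(3600) / 3600.0
        assert settling_slope(series(values), 3600) == pytest.approx(-1.0)

    def test_constant_first_hour_gives_zero(self):
        assert settling_slope(series(np.full(4000, 0.3)), 3600) == 0.0

    def test_linear_rise_final_window(self):
        values = np.concatenate([np.zeros(1000), np.arange(5400) / 5400.0])
        assert predeparture_slope(series(values), 5400) == pytest.approx(2 / 3.0,
                                                                         rel=1e-3)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="shorter than window"):
            settling_slope(series(np.zeros(100)), 3600)

    def test_unnormalized_series_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            settling_slope(series(np.zeros(4000), normalized=False), 3600)

    @given(st.integers(0, 2**31 - 1), st.floats(-5, 5), st.floats(0.1, 10))
    @settings(max_examples=30, deadline=None)
    def test_shift_invariance_and_scale_equivariance(self, seed, shift, scale):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=400)
        base = settling_slope(series(values), 300)
        shifted = settling_slope(series(values + shift), 300)
        scaled = settling_slope(series(values * scale), 300)
        assert shifted == pytest.approx(base, abs=1e-9)
        assert scaled == pytest.approx(base * scale, rel=1e-9, abs=1e-12)

    def test_agrees_with_naive_loop_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            values = rng.normal(0.5, 0.2, size=rng.integers(50, 300))
            s = series(values)
            w = len(values) // 2
            assert settling_slope(s, w) == pytest.approx(
                naive_slope_per_hour(values[:w]), abs=1e-9)
            assert predeparture_slope(s, w) == pytest.approx(
                naive_slope_per_hour(values[-w:]), abs=1e-9)


class TestNightCallingProportion:
    def test_all_zero_window(self):
        values = np.concatenate([np.ones(100), np.zeros(300), np.ones(150)])
        assert night_calling_proportion(series(values), 0.2, 100, 150) == 0.0

    def test_all_one_window(self):
        assert night_calling_proportion(series(np.ones(600)), 0.2, 100, 150) == 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        s = series(rng.uniform(size=500))
        p02 = night_calling_proportion(s, 0.2, 50, 50)
        p04 = night_calling_proportion(s, 0.4, 50, 50)
        assert p04 <= p02

    def test_agrees_with_naive_loop_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            values = rng.uniform(size=400)
            got = night_calling_proportion(series(values), 0.3, 60, 80)
            window = values[60:-80]
            want = sum(1 for v in window if v >= 0.3) / len(window)
            assert got == pytest.approx(want, abs=1e-12)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            night_calling_proportion(series(np.ones(100)), 0.2, 60, 60)

    def test_planted_call_seconds_recovered(self, night, night_npsd, cfg):
        """The measured proportion matches the planted fraction of
        call-containing seconds within +/- 0.02."""
        _, _, truth = night
        got = night_calling_proportion(night_npsd, cfg.call_threshold,
                                       cfg.settle_window_s,
                                       cfg.predeparture_window_s)
        counts = truth["per_second_call_count"]
        i0 = int(night_npsd.t0_s) + cfg.settle_window_s
        i1 = int(night_npsd.t0_s) + len(night_npsd) - cfg.predeparture_window_s
        planted = float(np.mean(counts[i0:i1] > 0))
        assert got == pytest.approx(planted, abs=0.02)


class TestGeneratorOracles:
    def test_settling_slope_tracks_planted_decay(self, cfg):
        """Pipeline slope is negative and within 15% of the slope of
        the ground-truth intensity series (realized call counts over
        the planted linear rate decay)."""
        scenario = NightScenario.compressed(240, seed=21,
                                            call_amplitude_jitter_db=0.0)
        audio, truth = simulate_night(scenario)
        npsd = normalize_night(trim_to_occupancy(
            band_psd_series(audio, cfg.band_call_hz),
            cfg.head_trim_s, cfg.tail_trim_s))
        got = settling_slope(npsd, cfg.settle_window_s)
        amp = 10 ** (scenario.call_amplitude_db / 20)
        power = (truth["per_second_call_count"] * amp**2 * 0.375 * 0.35
                 + truth["noise_rms_per_second"] ** 2 * 0.5)
        db = 10 * np.log10(power)
        i0 = int(npsd.t0_s)
        seg = db[i0: i0 + len(npsd)]
        nseg = (seg - seg.min()) / (seg.max() - seg.min())
        oracle = naive_slope_per_hour(nseg[: cfg.settle_window_s])
        assert got < 0
        assert got == pytest.approx(oracle, rel=0.15)

    @staticmethod
    def _sparse_crescendo(seed, boost):
        """Night whose crescendo sweeps the sparse-calling regime
        (per-second call probability rising from ~0.05 to near 1),
        where the dB series responds to the ramp steepness.  Once
        every second holds overlapping calls the dB slope saturates,
        so monotonicity in the planted slope is a sparse-regime
        property."""
        night = 0.05 * 3600.0          # 0.05 calls/s
        ramp = ((1.2 * 3600.0) - night) / (45.0 / 3600.0) * boost
        return NightScenario(
            duration_s=480.0, arrival_time_s=15.0,
            arrival_peak_rate=240 * 3600.0,
            arrival_decay_rate=240 * 3600.0 * 240,
            night_call_rate=night, departure_anchor_s=470.0,
            predeparture_len_s=45.0, predeparture_slope_truth=ramp,
            seed=seed)

    def test_predeparture_slope_monotone_in_crescendo(self):
        """A steeper planted crescendo yields a strictly larger
        pre-departure slope across 20 paired nights (same seed)."""
        wins = 0
        for seed in range(20):
            slopes = []
            for boost in (1.0, 2.5):
                audio, _ = simulate_night(self._sparse_crescendo(400 + seed, boost))
                psd = band_psd_series(audio, (1000, 3000))
                upto = dataclasses.replace(psd, values=psd.values[:470])
                slopes.append(predeparture_slope(normalize_night(upto), 45))
            wins += slopes[1] > slopes[0]
        assert wins == 20


class TestBackgroundNoise:
    def _planted_night(self, levels, seed=0):
        """Noise-only night apart from an arrival calling burst (the
        profile source): the three measurement windows are call-free,
        as in field nights with quiet, undisturbed birds."""
        dur = 480.0
        return simulate_night(NightScenario(
            duration_s=dur, arrival_time_s=30.0, arrival_peak_rate=7200 * 120.0,
            arrival_decay_rate=7200 * 240 * 120.0, night_call_rate=0.0,
            departure_anchor_s=dur - 5, predeparture_len_s=5.0,
            predeparture_slope_truth=0.0,
            noise_schedule=(
                (0.0, levels[0]),          # pre-arrival hour
                (60.0, levels[1]),         # night
                (400.0, levels[2]),        # pre-departure hour
            ),
            noise_level_db=levels[0], seed=seed,
        ))[0]

    def test_planted_levels_strictly_ordered(self):
        audio = self._planted_night((-30.0, -40.0, -50.0))
        pre, night, dep = background_noise_levels(
            audio, arrival_anchor_s=30.0, departure_calling_onset_s=455.0,
            window_s=25.0, night_window_s=(200.0, 260.0), profile_len_s=15.0)
        assert pre > night > dep

    def test_louder_overnight_than_prearrival(self):
        audio = self._planted_night((-45.0, -30.0, -45.0), seed=1)
        pre, night, dep = background_noise_levels(
            audio, arrival_anchor_s=30.0, departure_calling_onset_s=455.0,
            window_s=25.0, night_window_s=(200.0, 260.0), profile_len_s=15.0)
        assert night > pre

    def test_silent_recording_degenerates_to_equal_means(self):
        from roostcall import AudioNight
        audio = AudioNight(samples=np.zeros(8000 * 480), sample_rate=8000.0)
        out = background_noise_levels(audio, 30.0, 455.0, window_s=25.0,
                                      night_window_s=(200.0, 260.0),
                                      profile_len_s=15.0)
        assert out == (0.0, 0.0, 0.0)

    def test_window_outside_recording_rejected(self):
        audio = self._planted_night((-40.0, -40.0, -40.0))
        with pytest.raises(ValueError, match="outside recording"):
            background_noise_levels(audio, 10.0, 470.0, window_s=60.0)


class TestOnsetDetection:
    def test_finds_first_sustained_run(self):
        values = np.zeros(600)
        values[450:530] = 0.5
        onset = detect_departure_calling_onset(series(values, t0=100.0),
                                               threshold=0.2, run_s=60,
                                               window_s=300)
        assert onset == 100.0 + 450

    def test_falls_back_to_window_start(self):
        onset = detect_departure_calling_onset(series(np.zeros(600)),
                                               threshold=0.2, run_s=60,
                                               window_s=300)
        assert onset == 300.0


class TestAssemble:
    def test_deterministic(self, night, cfg):
        _, audio, _ = night
        a = assemble_night_metrics(audio, {"site": "s1", "date": "d"}, cfg)
        b = assemble_night_metrics(audio, {"site": "s1", "date": "d"}, cfg)
        assert a == b

    def test_missing_light_flagged_absent(self, night, cfg):
        """A night without light data (logger failure at the urban
        site) still yields metrics, with light marked absent."""
        _, audio, _ = night
        m = assemble_night_metrics(audio, {"site": "moor", "date": "d",
                                           "roost_size": 500}, cfg)
        assert not m.light_present and math.isnan(m.light_mean)
        assert 0.0 <= m.night_call_prop <= 1.0
        assert m.night_call_prop_alt <= m.night_call_prop

    def test_stage_labelled_errors(self, cfg):
        from roostcall import AudioNight
        tiny = AudioNight(samples=np.zeros(8000 * 20), sample_rate=8000.0)
        with pytest.raises(RuntimeError, match="stage '"):
            assemble_night_metrics(tiny, {}, cfg)
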