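"""Shared fixtures: a compressed-time synthetic roost-night and the
matching pipeline configuration.

Tests run on time-compressed nights (16 h squeezed by a factor of 240
into 4 min of 8 kHz audio) with every analysis window scaled by the
same factor; rates scale up so expected call counts per phase match the
full-scale night.
"""

import numpy as np
import pytest

from roostcall import NightScenario, PipelineConfig, simulate_night
from roostcall.acoustic import band_psd_series, normalize_night, trim_to_occupancy

TIME_SCALE = 240


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig().scaled(TIME_SCALE)


@pytest.fixture(scope="session")
def night():
    """(scenario, audio, ground_truth) for one compressed roost-night."""
    scenario = NightScenario.compressed(TIME_SCALE, seed=11)
    audio, truth = simulate_night(scenario)
    return scenario, audio, truth


@pytest.fixture(scope="session")
def night_npsd(night, cfg):
    """The night's normalized, trimmed call-band series (no noise
    reduction: the raw chain suffices for ground-truth comparisons)."""
    _, audio, _ = night
    psd = band_psd_series(audio, cfg.band_call_hz)
    return normalize_night(trim_to_occupancy(psd, cfg.head_trim_s, cfg.tail_trim_s))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
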