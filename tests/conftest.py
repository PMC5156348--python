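import numpy as np
import pytest

from nestcare import simulate as sim
from nestcare.ethogram import (FULL_DAY, FeedingEvent, NestRecording,
                               StateInterval)


def rasterized_length(intervals, window, gaps=()):
    """Independent 1s-grid oracle for interval measure inside a window.

    Valid for integer-second endpoints: counts grid seconds [s, s+1) that
    are covered by some interval, lie in the window and miss every gap.
    """
    lo, hi = int(window[0]), int(window[1])
    covered = np.zeros(hi - lo, dtype=bool)
    for s, e in intervals:
        a, b = max(int(s), lo), min(int(e), hi)
        if b > a:
            covered[a - lo:b - lo] = True
    visible = np.ones(hi - lo, dtype=bool)
    for s, e in gaps:
        a, b = max(int(s), lo), min(int(e), hi)
        if b > a:
            visible[a - lo:b - lo] = False
    return float((covered & visible).sum()), float(visible.sum())


def random_integer_intervals(rng, n, lo, hi, max_len=3600):
    out = []
    for _ in range(n):
        s = int(rng.integers(lo, hi - 1))
        e = int(min(s + 1 + rng.integers(0, max_len), hi))
        out.append((float(s), float(e)))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_recording():
    """Full-day incubation recording with simple hand-laid tracks."""
    start, end = FULL_DAY
    intervals = [
        StateInterval("male", "care", start, start + 100),
        StateInterval("male", "inside", start + 100, start + 200),
        StateInterval("female", "care", start + 50, start + 150),
        StateInterval("female", "care", start + 4000, start + 8000),
    ]
    return NestRecording(nest_id="N1", stage="incubation", stage_day=3,
                         record_start=start, record_end=end,
                         intervals=intervals)


@pytest.fixture(scope="session")
def paperlike_corpus():
    cfg = sim.preset_paperlike()
    cfg.seed = 1
    return sim.simulate_population(cfg)
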