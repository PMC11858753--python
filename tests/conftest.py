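from datetime import datetime

import numpy as np
import pytest

from circasleep import ActigraphyRecording, BinnedSeries

MIDNIGHT = datetime(2021, 3, 1, 0, 0, 0)


@pytest.fixture
def square_wave_recording() -> ActigraphyRecording:
    """7 days of 1-min epochs: 100 counts for hours 8-17, 0 elsewhere."""
    hours = (np.arange(7 * 1440) // 60) % 24
    activity = np.where((hours >= 8) & (hours <= 17), 100.0, 0.0)
    return ActigraphyRecording("sq", MIDNIGHT, 60, activity)


@pytest.fixture
def repeated_day_series() -> BinnedSeries:
    """7 identical copies of one non-constant 24-bin day."""
    rng = np.random.default_rng(7)
    day = rng.uniform(0, 100, size=24)
    return BinnedSeries(np.tile(day, 7), bins_per_day=24, days=7)


def hourly_series(values: np.ndarray, days: int) -> BinnedSeries:
    return BinnedSeries(np.asarray(values, float), bins_per_day=24, days=days)
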