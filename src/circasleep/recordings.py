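"""Containers for epoch-level actigraphy data and day-binned series.

An :class:`ActigraphyRecording` holds the raw, uniformly sampled activity
counts for one subject; a :class:`BinnedSeries` is the day-aligned,
hour-of-day binned view that the non-parametric circadian statistics
(IS, IV, RA) are defined on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np

__all__ = ["ActigraphyRecording", "BinnedSeries"]

SECONDS_PER_DAY = 86_400


@dataclass
class ActigraphyRecording:
    """Epoch-level activity time series for one subject.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    start_time : datetime
        Local calendar timestamp of the first epoch.
    epoch_seconds : int
        Seconds per epoch; must divide 3600 so epochs nest inside hours.
    activity : ndarray of float
        Non-negative activity counts, one per epoch. Missing epochs may
        hold any placeholder value (NaN by convention).
    missing_mask : ndarray of bool
        True where the epoch is missing. Defaults to all observed.
    """

    subject_id: str
    start_time: datetime
    epoch_seconds: int
    activity: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.ndim != 1:
            raise ValueError("activity must be one-dimensional")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.activity.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.activity.shape:
            raise ValueError("missing_mask must match activity length")
        if not isinstance(self.epoch_seconds, (int, np.integer)) or self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be a positive integer")
        if 3600 % int(self.epoch_seconds) != 0:
            raise ValueError(
                f"epoch_seconds={self.epoch_seconds} must divide 3600 "
                "(epochs must nest inside hours)"
            )
        observed = self.activity[~self.missing_mask]
        if observed.size and (np.isnan(observed).any() or (observed < 0).any()):
            raise ValueError("observed activity values must be finite and >= 0")

    @property
    def n_epochs(self) -> int:
        return int(self.activity.size)

    @property
    def epochs_per_day(self) -> int:
        return SECONDS_PER_DAY // int(self.epoch_seconds)

    def epoch_times(self) -> list[datetime]:
        """Timestamps of every epoch (start-of-epoch convention)."""
        step = timedelta(seconds=int(self.epoch_seconds))
        return [self.start_time + i * step for i in range(self.n_epochs)]


@dataclass
class BinnedSeries:
    """Day-aligned binned activity: ``n = bins_per_day * days`` values.

    ``values[d * p + h]`` is bin-of-day ``h`` on day ``d`` with
    ``p = bins_per_day``. NaN marks a missing bin.
    """

    values: np.ndarray
    bins_per_day: int
    days: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.days < 1:
            raise ValueError("BinnedSeries needs at least one complete day")
        if self.values.size != self.bins_per_day * self.days:
            raise ValueError(
                f"length {self.values.size} != bins_per_day*days "
                f"({self.bins_per_day}*{self.days})"
            )

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def bin_hours(self) -> float:
        """Width of one bin in hours."""
        return 24.0 / self.bins_per_day

    def by_day(self) -> np.ndarray:
        """Return a (days, bins_per_day) matrix view of the values."""
        return self.values.reshape(self.days, self.bins_per_day)

    def daily_profile(self) -> np.ndarray:
        """Average day: mean over days for each bin-of-day (NaN-aware)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.by_day(), axis=0)
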