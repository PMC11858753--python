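"""Non-parametric circadian rhythm analysis (NPCRA) and the circadian
function index (CFI).

The three classical non-parametric statistics are computed from a
day-binned activity series:

* **IS** (interdaily stability): ratio of the variance of the average
  24 h profile to the total variance. 1 means the daily pattern repeats
  perfectly; values near 0 indicate noise.
* **IV** (intradaily variability): mean squared successive difference
  divided by the overall variance. Near 0 for a smooth sinusoid, near 2
  for white noise; anti-correlated series can exceed 2.
* **RA** (relative amplitude): ``(M10 - L5) / (M10 + L5)`` where M10 and
  L5 are the mean activity of the most active 10 and least active 5
  consecutive hours of the average day (circular windows).

The CFI is the arithmetic mean of IS, the inverted-and-normalized IV
(``clip(1 - IV/2, 0, 1)``; 1 = perfect sinusoid, 0 = noise-level
fragmentation) and RA, so it runs from 0 (no circadian rhythmicity) to 1
(a robust rhythm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .recordings import SECONDS_PER_DAY, ActigraphyRecording, BinnedSeries

__all__ = [
    "NPCRAResult",
    "bin_recording",
    "interdaily_stability",
    "intradaily_variability",
    "relative_amplitude",
    "cfi_compose",
    "npcra",
]

logger = logging.getLogger(__name__)

#: Minimum number of consecutive recorded nights recommended for stable
#: NPCRA statistics.
MIN_NIGHTS = 6


@dataclass(frozen=True)
class NPCRAResult:
    """Per-subject non-parametric circadian statistics."""

    IS: float
    IV: float
    RA: float
    M10: float
    L5: float
    M10_onset_hour: float
    L5_onset_hour: float
    IV_inv_norm: float
    CFI: float
    n_days: int

    def to_dict(self) -> dict:
        return {
            "IS": self.IS,
            "IV": self.IV,
            "RA": self.RA,
            "M10": self.M10,
            "L5": self.L5,
            "M10_onset_hour": self.M10_onset_hour,
            "L5_onset_hour": self.L5_onset_hour,
            "IV_inv_norm": self.IV_inv_norm,
            "CFI": self.CFI,
            "n_days": self.n_days,
        }


def _trim_to_complete_days(rec: ActigraphyRecording) -> tuple[int, int, int]:
    """Return (start_index, n_days, epochs_per_day) after trimming partial
    leading/trailing days. Day boundary is local midnight of start_time."""
    epd = rec.epochs_per_day
    seconds_into_day = (
        rec.start_time.hour * 3600 + rec.start_time.minute * 60 + rec.start_time.second
    )
    if seconds_into_day % rec.epoch_seconds != 0:
        raise ValueError("start_time is not aligned to the epoch grid")
    offset_epochs = seconds_into_day // rec.epoch_seconds
    lead = 0 if offset_epochs == 0 else epd - offset_epochs
    n_days = max(0, (rec.n_epochs - lead) // epd)
    return lead, n_days, epd


def bin_recording(
    rec: ActigraphyRecording,
    bins_per_day: int = 24,
    max_missing_fraction: float = 0.2,
    missing_policy: str = "error",
) -> BinnedSeries:
    """Trim to complete days and average epochs into ``bins_per_day`` bins.

    Partial leading/trailing days are discarded (day boundary at local
    midnight). Each bin is the mean of its non-missing epochs; a bin with
    at least half of its epochs missing is itself missing, which under the
    default ``missing_policy='error'`` aborts (the IS/IV formulas assume
    complete balanced days). ``missing_policy='impute'`` fills missing
    bins with the bin-of-day mean and logs a warning.
    """
    if missing_policy not in ("error", "impute"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    epd = SECONDS_PER_DAY // rec.epoch_seconds
    if epd % bins_per_day != 0:
        raise ValueError(
            f"bins_per_day={bins_per_day} must divide epochs per day ({epd})"
        )
    lead, n_days, epd = _trim_to_complete_days(rec)
    if n_days < 1:
        raise ValueError("recording contains zero complete days after trimming")

    act = rec.activity[lead : lead + n_days * epd].astype(float).copy()
    miss = rec.missing_mask[lead : lead + n_days * epd]
    frac_missing = float(miss.mean())
    if frac_missing > max_missing_fraction:
        raise ValueError(
            f"missing fraction {frac_missing:.3f} exceeds allowed "
            f"{max_missing_fraction:.3f}"
        )

    per_bin = epd // bins_per_day
    act[miss] = np.nan
    grid = act.reshape(n_days * bins_per_day, per_bin)
    miss_count = miss.reshape(n_days * bins_per_day, per_bin).sum(axis=1)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        binned = np.nanmean(grid, axis=1)
    # >= 50% missing epochs -> the bin itself is missing
    binned[miss_count * 2 >= per_bin] = np.nan

    if np.isnan(binned).any():
        bad = int(np.flatnonzero(np.isnan(binned))[0])
        day, bin_of_day = divmod(bad, bins_per_day)
        if missing_policy == "error":
            raise ValueError(
                f"bin {bin_of_day} of day {day} is missing "
                "(>= 50% of its epochs are missing)"
            )
        profile = np.nanmean(binned.reshape(n_days, bins_per_day), axis=0)
        if np.isnan(profile).any():
            raise ValueError(
                "cannot impute: some bin-of-day is missing on every day"
            )
        idx = np.flatnonzero(np.isnan(binned))
        binned[idx] = profile[idx % bins_per_day]
        logger.warning(
            "imputed %d missing bins with bin-of-day means", idx.size
        )
    return BinnedSeries(values=binned, bins_per_day=bins_per_day, days=n_days)


def interdaily_stability(s: BinnedSeries) -> float:
    """IS: between-bin-of-day variance over total variance, in [0, 1].

    ``IS = [sum_h (xbar_h - xbar)^2 / p] / [sum_i (x_i - xbar)^2 / n]``
    with ``xbar_h`` the mean over days of bin-of-day ``h``.
    """
    if s.days < 2:
        raise ValueError("IS requires at least two complete days")
    x = s.values
    if np.isnan(x).any():
        raise ValueError("IS requires a complete series (no missing bins)")
    xbar = x.mean()
    total = np.sum((x - xbar) ** 2) / x.size
    if total == 0:
        raise ValueError("undefined IS: series is constant (zero variance)")
    profile = s.by_day().mean(axis=0)
    between = np.sum((profile - xbar) ** 2) / s.bins_per_day
    # mathematically between-SS <= total-SS; clip float round-off
    return float(min(between / total, 1.0))


def intradaily_variability(s: BinnedSeries) -> float:
    """IV: normalized mean squared successive difference, >= 0.

    ``IV = [sum_{i>=2} (x_i - x_{i-1})^2 / (n-1)] / [sum_i (x_i - xbar)^2 / n]``
    """
    x = s.values
    if x.size < 2:
        raise ValueError("IV requires at least two bins")
    if np.isnan(x).any():
        raise ValueError("IV requires a complete series (no missing bins)")
    total = np.sum((x - x.mean()) ** 2) / x.size
    if total == 0:
        raise ValueError("undefined IV: series is constant (zero variance)")
    mssd = np.sum(np.diff(x) ** 2) / (x.size - 1)
    return float(mssd / total)


def relative_amplitude(
    s: BinnedSeries, m_hours: int = 10, l_hours: int = 5
) -> tuple[float, float, float, float, float]:
    """RA and its components from the average 24 h profile.

    Scans every window of ``m_hours`` (default 10) and ``l_hours``
    (default 5) consecutive hours with circular wrap-around on the mean
    daily profile. Returns ``(RA, M10, L5, M10_onset_hour, L5_onset_hour)``
    with ``RA = (M10 - L5) / (M10 + L5)`` and RA = 0 when the profile is
    identically zero.
    """
    profile = s.daily_profile()
    if np.isnan(profile).any():
        raise ValueError("RA requires every bin-of-day observed on some day")
    if (profile < 0).any():
        raise ValueError("activity values must be non-negative")
    p = s.bins_per_day
    for hours in (m_hours, l_hours):
        if (hours * p) % 24 != 0:
            raise ValueError(
                f"a {hours} h window is not a whole number of bins at "
                f"{p} bins/day"
            )
    m_bins = m_hours * p // 24
    l_bins = l_hours * p // 24
    wrapped = np.concatenate([profile, profile])
    csum = np.concatenate([[0.0], np.cumsum(wrapped)])

    def window_means(width: int) -> np.ndarray:
        return (csum[width : width + p] - csum[:p]) / width

    m_means = window_means(m_bins)
    l_means = window_means(l_bins)
    i_m = int(np.argmax(m_means))
    i_l = int(np.argmin(l_means))
    m10 = float(m_means[i_m])
    l5 = float(l_means[i_l])
    ra = 0.0 if m10 + l5 == 0 else (m10 - l5) / (m10 + l5)
    return ra, m10, l5, i_m * 24.0 / p, i_l * 24.0 / p


def cfi_compose(IS: float, IV: float, RA: float) -> tuple[float, float]:
    """Compose the circadian function index from IS, IV and RA.

    IV is inverted and normalized to [0, 1] as ``clip(1 - IV/2, 0, 1)``
    (1 = perfect sinusoid, 0 = noise-level or worse fragmentation); the
    CFI is the plain average of IS, this inverted IV, and RA.

    Returns ``(IV_inv_norm, CFI)``.
    """
    if not 0.0 <= IS <= 1.0:
        raise ValueError(f"IS={IS} outside [0, 1]")
    if IV < 0.0:
        raise ValueError(f"IV={IV} must be >= 0")
    if not 0.0 <= RA <= 1.0:
        raise ValueError(f"RA={RA} outside [0, 1]")
    iv_inv = float(np.clip(1.0 - IV / 2.0, 0.0, 1.0))
    cfi = (IS + iv_inv + RA) / 3.0
    return iv_inv, float(cfi)


def npcra(
    rec: ActigraphyRecording,
    bins_per_day: int = 24,
    min_nights: int = MIN_NIGHTS,
    allow_short: bool = False,
    max_missing_fraction: float = 0.2,
    missing_policy: str = "error",
) -> NPCRAResult:
    """Full pipeline: bin, compute IS/IV/RA, compose the CFI.

    Recordings shorter than ``min_nights`` complete days (default 6, the
    minimum recommended for stable NPCRA statistics) are rejected unless
    ``allow_short=True``, which downgrades the rejection to a warning.
    """
    s = bin_recording(
        rec,
        bins_per_day=bins_per_day,
        max_missing_fraction=max_missing_fraction,
        missing_policy=missing_policy,
    )
    if s.days < min_nights:
        msg = (
            f"recording has {s.days} complete days; a minimum of "
            f"{min_nights} consecutive nights is required for NPCRA"
        )
        if not allow_short:
            raise ValueError(msg)
        logger.warning("%s (proceeding: allow_short=True)", msg)
    IS = interdaily_stability(s)
    IV = intradaily_variability(s)
    RA, m10, l5, m_on, l_on = relative_amplitude(s)
    iv_inv, cfi = cfi_compose(IS, IV, RA)
    return NPCRAResult(
        IS=IS,
        IV=IV,
        RA=RA,
        M10=m10,
        L5=l5,
        M10_onset_hour=m_on,
        L5_onset_hour=l_on,
        IV_inv_norm=iv_inv,
        CFI=cfi,
        n_days=s.days,
    )
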