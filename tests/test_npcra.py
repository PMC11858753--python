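"""Unit and property tests for the non-parametric circadian statistics."""

from datetime import datetime

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circasleep import (
    ActigraphyRecording,
    BinnedSeries,
    bin_recording,
    cfi_compose,
    interdaily_stability,
    intradaily_variability,
    npcra,
    relative_amplitude,
)

MIDNIGHT = datetime(2021, 3, 1)


# ---------------------------------------------------------------- oracles

def is_bruteforce(values: np.ndarray, p: int) -> float:
    """IS straight from the definition, written independently."""
    x = np.asarray(values, float)
    n = x.size
    d = n // p
    xbar = x.mean()
    hour_means = [x[h::p].mean() for h in range(p)]
    num = sum((m - xbar) ** 2 for m in hour_means) / p
    den = sum((xi - xbar) ** 2 for xi in x) / n
    return num / den


def iv_bruteforce(values: np.ndarray) -> float:
    x = np.asarray(values, float)
    n = x.size
    num = sum((x[i] - x[i - 1]) ** 2 for i in range(1, n)) / (n - 1)
    den = sum((xi - x.mean()) ** 2 for xi in x) / n
    return num / den


def ra_bruteforce(profile: np.ndarray) -> tuple[float, float, float]:
    """Exhaustive scan over every wrapped 10 h / 5 h window."""
    p = len(profile)
    wrapped = np.concatenate([profile, profile])
    m10 = max(wrapped[i : i + 10 * p // 24].mean() for i in range(p))
    l5 = min(wrapped[i : i + 5 * p // 24].mean() for i in range(p))
    return (m10 - l5) / (m10 + l5) if m10 + l5 else 0.0, m10, l5


# ----------------------------------------------------------- bin_recording

def test_binning_constant_signal():
    rec = ActigraphyRecording("c", MIDNIGHT, 60, np.full(1440, 5.0))
    s = bin_recording(rec, bins_per_day=24)
    assert s.days == 1
    assert np.allclose(s.values, 5.0)
    assert s.n == 24


def test_binning_trims_partial_trailing_day():
    rec = ActigraphyRecording("t", MIDNIGHT, 60, np.full(2 * 1440 + 180, 1.0))
    s = bin_recording(rec, bins_per_day=24)
    assert s.days == 2


def test_binning_trims_partial_leading_day():
    # start at 22:00 -> the two leading hours belong to an incomplete day
    rec = ActigraphyRecording(
        "l", datetime(2021, 3, 1, 22), 60, np.full(120 + 1440, 3.0)
    )
    s = bin_recording(rec, bins_per_day=24)
    assert s.days == 1


def test_binning_averages_within_hour():
    activity = np.tile([0.0, 10.0], 1440 // 2 * 2)[: 2 * 1440]
    rec = ActigraphyRecording("a", MIDNIGHT, 60, activity)
    s = bin_recording(rec, bins_per_day=24)
    assert np.allclose(s.values, 5.0)


def test_binning_zero_complete_days_errors():
    rec = ActigraphyRecording("z", MIDNIGHT, 60, np.ones(1000))
    with pytest.raises(ValueError, match="zero complete days"):
        bin_recording(rec)


def test_binning_missing_bin_errors_with_location():
    activity = np.ones(1440)
    missing = np.zeros(1440, bool)
    missing[5 * 60 : 6 * 60] = True  # hour 5 fully missing
    rec = ActigraphyRecording("m", MIDNIGHT, 60, activity, missing)
    with pytest.raises(ValueError, match="bin 5"):
        bin_recording(rec, max_missing_fraction=0.5)


def test_binning_impute_policy_fills_from_profile():
    activity = np.tile(np.arange(24.0).repeat(60), 3)
    missing = np.zeros(3 * 1440, bool)
    missing[1440 + 5 * 60 : 1440 + 6 * 60] = True  # day 1, hour 5
    rec = ActigraphyRecording("i", MIDNIGHT, 60, activity, missing)
    s = bin_recording(rec, missing_policy="impute", max_missing_fraction=0.5)
    assert s.values[24 + 5] == pytest.approx(5.0)  # bin-of-day mean


# ------------------------------------------------------------------- IS

def test_is_identical_days_is_one(repeated_day_series):
    assert interdaily_stability(repeated_day_series) == pytest.approx(1.0)


def test_is_constant_series_errors():
    s = BinnedSeries(np.full(48, 3.0), 24, 2)
    with pytest.raises(ValueError, match="undefined IS"):
        interdaily_stability(s)


def test_is_matches_bruteforce_on_gaussian_noise():
    rng = np.random.default_rng(11)
    x = rng.normal(size=24 * 30)
    s = BinnedSeries(x, 24, 30)
    assert interdaily_stability(s) == pytest.approx(is_bruteforce(x, 24), rel=1e-12)


# ------------------------------------------------------------------- IV

def test_iv_pure_cosine_closed_form():
    p, d = 24, 30
    n = p * d
    x = np.cos(2 * np.pi * np.arange(n) / p)
    s = BinnedSeries(x, p, d)
    iv = intradaily_variability(s)
    closed = (n / (n - 1)) * 2 * (1 - np.cos(2 * np.pi / p))
    assert iv == pytest.approx(closed, abs=1e-3)
    assert iv == pytest.approx(iv_bruteforce(x), rel=1e-12)


def test_iv_alternating_series_is_four():
    x = np.tile([2.0, 8.0], 24)
    s = BinnedSeries(x, 24, 2)
    assert intradaily_variability(s) == pytest.approx(4.0)


def test_iv_gaussian_noise_near_two():
    rng = np.random.default_rng(5)
    x = rng.normal(size=10_000)
    s = BinnedSeries(x, 20, 500)
    assert intradaily_variability(s) == pytest.approx(2.0, abs=0.05)


def test_iv_constant_series_errors():
    with pytest.raises(ValueError, match="undefined IV"):
        intradaily_variability(BinnedSeries(np.zeros(48), 24, 2))


# ------------------------------------------------------------------- RA

def test_ra_square_wave_is_one(square_wave_recording):
    s = bin_recording(square_wave_recording)
    ra, m10, l5, m_on, _ = relative_amplitude(s)
    assert (ra, m10, l5) == (1.0, 100.0, 0.0)
    assert m_on == 8.0


def test_ra_constant_signal_is_zero():
    s = BinnedSeries(np.full(48, 7.0), 24, 2)
    ra, m10, l5, *_ = relative_amplitude(s)
    assert ra == 0.0
    assert m10 == l5 == pytest.approx(7.0)


def test_ra_all_zero_profile_is_zero_by_convention():
    ra, *_ = relative_amplitude(BinnedSeries(np.zeros(48), 24, 2))
    assert ra == 0.0


def test_ra_cosine_profile_matches_bruteforce():
    h = np.arange(24)
    profile = 1 + np.cos(2 * np.pi * (h - 14) / 24)
    s = BinnedSeries(np.tile(profile, 3), 24, 3)
    ra, m10, l5, *_ = relative_amplitude(s)
    ra_ref, m10_ref, l5_ref = ra_bruteforce(profile)
    assert ra == pytest.approx(ra_ref, rel=1e-12)
    assert m10 == pytest.approx(m10_ref) and l5 == pytest.approx(l5_ref)


def test_ra_negative_values_error():
    s = BinnedSeries(np.linspace(-1, 1, 48), 24, 2)
    with pytest.raises(ValueError, match="non-negative"):
        relative_amplitude(s)


# ------------------------------------------------------------------ CFI

@pytest.mark.parametrize(
    "IS, IV, RA, iv_inv_expect, cfi_expect",
    [
        (1.0, 0.0, 1.0, 1.0, 1.0),
        (0.0, 2.0, 0.0, 0.0, 0.0),
        (0.6, 0.8, 0.7, 0.6, 0.6333333333),
        (0.5, 3.0, 0.5, 0.0, 0.3333333333),
    ],
)
def test_cfi_compose_examples(IS, IV, RA, iv_inv_expect, cfi_expect):
    iv_inv, cfi = cfi_compose(IS, IV, RA)
    assert iv_inv == pytest.approx(iv_inv_expect)
    assert cfi == pytest.approx(cfi_expect)


@pytest.mark.parametrize("IS, IV, RA", [(-0.1, 0, 0.5), (0.5, -1, 0.5), (0.5, 0, 1.2)])
def test_cfi_compose_rejects_out_of_range(IS, IV, RA):
    with pytest.raises(ValueError):
        cfi_compose(IS, IV, RA)


# --------------------------------------------------------- full pipeline

def test_npcra_square_wave_end_to_end(square_wave_recording):
    res = npcra(square_wave_recording)
    s = bin_recording(square_wave_recording)
    expect_is = interdaily_stability(s)
    expect_iv = intradaily_variability(s)
    _, expect_cfi = cfi_compose(expect_is, expect_iv, 1.0)
    assert res.IS == pytest.approx(1.0)
    assert res.RA == pytest.approx(1.0)
    assert res.CFI == pytest.approx(expect_cfi)
    assert res.n_days == 7


def test_npcra_rejects_short_recording():
    rec = ActigraphyRecording(
        "s", MIDNIGHT, 60,
        100 + 50 * np.sin(2 * np.pi * np.arange(5 * 1440) / 1440),
    )
    with pytest.raises(ValueError, match="6 consecutive nights"):
        npcra(rec)


def test_npcra_short_recording_override_warns(caplog):
    rec = ActigraphyRecording(
        "s", MIDNIGHT, 60,
        100 + 50 * np.sin(2 * np.pi * np.arange(5 * 1440) / 1440),
    )
    with caplog.at_level("WARNING"):
        res = npcra(rec, allow_short=True)
    assert res.n_days == 5
    assert any("6 consecutive nights" in m for m in caplog.messages)


# ----------------------------------------------------------- properties

@st.composite
def binned_series(draw):
    d = draw(st.integers(min_value=2, max_value=5))
    vals = draw(
        st.lists(
            st.floats(0, 1000, allow_nan=False, width=32),
            min_size=24 * d, max_size=24 * d,
        )
    )
    x = np.asarray(vals, float)
    if np.std(x) == 0:
        x[0] += 1.0
    return BinnedSeries(x, 24, d)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(binned_series())
def test_is_bounded_and_scale_invariant(s):
    v = interdaily_stability(s)
    assert 0.0 <= v <= 1.0 + 1e-12
    scaled = BinnedSeries(s.values * 3.7, s.bins_per_day, s.days)
    assert interdaily_stability(scaled) == pytest.approx(v, rel=1e-9)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(binned_series())
def test_iv_shift_and_scale_invariant(s):
    v = intradaily_variability(s)
    assert v >= 0.0
    shifted = BinnedSeries(s.values + 123.0, s.bins_per_day, s.days)
    scaled = BinnedSeries(s.values * 0.25, s.bins_per_day, s.days)
    assert intradaily_variability(shifted) == pytest.approx(v, rel=1e-6)
    assert intradaily_variability(scaled) == pytest.approx(v, rel=1e-9)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(binned_series())
def test_ra_matches_exhaustive_scan(s):
    ra, m10, l5, *_ = relative_amplitude(s)
    ra_ref, m10_ref, l5_ref = ra_bruteforce(s.daily_profile())
    assert ra == pytest.approx(ra_ref, abs=1e-9)
    assert 0.0 <= ra <= 1.0


def test_cfi_is_exact_mean_of_components():
    rng = np.random.default_rng(3)
    for _ in range(50):
        IS, RA = rng.uniform(0, 1, 2)
        IV = rng.uniform(0, 3)
        iv_inv, cfi = cfi_compose(IS, IV, RA)
        assert cfi == (IS + iv_inv + RA) / 3


def test_median_cfi_does_not_increase_with_noise():
    from circasleep import RhythmParams, generate_recording

    medians = []
    for noise in (10.0, 80.0, 200.0):
        cfis = []
        for seed in range(7):
            p = RhythmParams(noise_sd=noise, seed=seed, days=7)
            cfis.append(npcra(generate_recording(p)).CFI)
        medians.append(np.median(cfis))
    assert medians[0] >= medians[1] - 1e-6
    assert medians[1] >= medians[2] - 1e-6
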