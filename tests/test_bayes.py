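"""Tests for posterior summaries, support labels and the hierarchical fits."""

import numpy as np
import pandas as pd
import pytest

from circasleep import (
    McmcConfig,
    PriorSet,
    StudyGenParams,
    compare_models,
    fit_cfi_model,
    fit_sleep_model,
    generate_study_table,
    group_contrast,
    summarize_posterior,
    support_classification,
)

FAST = McmcConfig(n_chains=2, n_warmup=600, n_keep=200, seed=0,
                  check_convergence=False)


# ------------------------------------------------------ support labels

@pytest.mark.parametrize(
    "pct, label",
    [
        (98.4, "strong"), (100.0, "strong"), (95.0, "support"),
        (95.0001, "strong"), (90.5, "support"), (90.0, "weak"),
        (87.0, "weak"), (85.0, "none"), (50.0, "none"), (0.0, "none"),
    ],
)
def test_support_classification_thresholds(pct, label):
    assert support_classification(pct) == label


def test_support_classification_rejects_out_of_range():
    for bad in (-1.0, 101.0):
        with pytest.raises(ValueError):
            support_classification(bad)


def test_support_labels_partition_the_range():
    grid = np.linspace(0, 100, 2001)
    labels = {support_classification(p) for p in grid}
    assert labels == {"none", "weak", "support", "strong"}


# ------------------------------------------------------------ summaries

def test_summary_symmetric_draws_half_negative():
    draws = np.tile([-1.0, -1.0, 1.0, 1.0], 300)
    s = summarize_posterior(draws)
    assert s.pct_negative == pytest.approx(50.0)
    assert s.estimate == pytest.approx(0.0)


def test_summary_matches_normal_quantiles():
    rng = np.random.default_rng(0)
    s = summarize_posterior(rng.standard_normal(100_000))
    assert s.ci95[0] == pytest.approx(-1.96, abs=0.03)
    assert s.ci95[1] == pytest.approx(1.96, abs=0.03)
    assert s.ci89[0] == pytest.approx(-1.598, abs=0.03)
    # 89% interval nested inside the 95% interval
    assert s.ci95[0] < s.ci89[0] < s.ci89[1] < s.ci95[1]


def test_summary_interval_has_nominal_content():
    rng = np.random.default_rng(1)
    draws = rng.standard_normal(50_000)
    s = summarize_posterior(draws[:25_000])
    held_out = draws[25_000:]
    inside = np.mean((held_out >= s.ci89[0]) & (held_out <= s.ci89[1]))
    assert inside == pytest.approx(0.89, abs=0.01)


def test_summary_is_permutation_invariant():
    rng = np.random.default_rng(2)
    draws = rng.normal(size=5000)
    a = summarize_posterior(draws)
    b = summarize_posterior(rng.permutation(draws))
    assert b.estimate == pytest.approx(a.estimate, rel=1e-12)
    assert a.ci89 == b.ci89 and a.ci95 == b.ci95 and a.pct_negative == b.pct_negative


def test_summary_rejects_empty_and_tiny_inputs():
    with pytest.raises(ValueError):
        summarize_posterior(np.array([]))
    with pytest.raises(ValueError):
        summarize_posterior(np.ones(10))


# -------------------------------------------------------- sleep models

def test_prior_only_fit_returns_the_duration_prior():
    df = generate_study_table(StudyGenParams(seed=0))
    fit = fit_sleep_model(df, prior_only=True, mcmc=FAST)
    s = fit.summaries["intercept"]
    assert s.estimate == pytest.approx(8.0, abs=0.1)
    assert s.se == pytest.approx(1.0, abs=0.1)


def test_parameter_recovery_society_effect():
    g = StudyGenParams(seed=12)
    df = generate_study_table(g)
    fit = fit_sleep_model(df, mcmc=McmcConfig(seed=12))
    s = fit.summaries["society_nonindustrial"]
    assert abs(s.estimate - g.true_beta_society) < 2 * s.se
    assert max(fit.rhat.values()) < 1.01


def test_noise_free_group_offset_is_recovered():
    g = StudyGenParams(country_sd=0.0, residual_sd=0.05,
                       true_beta_age=0.0, true_beta_male=0.0,
                       true_beta_society=-1.0, seed=4)
    df = generate_study_table(g)
    fit = fit_sleep_model(df, mcmc=FAST)
    c = group_contrast(fit)
    assert c.estimate == pytest.approx(1.0, abs=0.1)
    assert c.parameter == "industrial_minus_nonindustrial"


def test_single_country_is_unidentifiable():
    df = generate_study_table(StudyGenParams(seed=0))
    df["country"] = "onlyland"
    with pytest.raises(ValueError, match="two countries"):
        fit_sleep_model(df, mcmc=FAST)


def test_constant_society_scale_is_unidentifiable():
    df = generate_study_table(StudyGenParams(seed=0))
    df["society_scale"] = "industrial"
    with pytest.raises(ValueError, match="unidentifiable"):
        fit_sleep_model(df, mcmc=FAST)


def test_missing_efficiency_outcome_refused():
    df = generate_study_table(StudyGenParams(seed=0))  # duration-only table
    with pytest.raises(ValueError, match="outcome_efficiency"):
        fit_sleep_model(df, outcome="efficiency", mcmc=FAST)


# ----------------------------------------------------------- CFI model

def _cfi_table(n=160, beta_soc=-0.07, beta_age=0.0, seed=0):
    rng = np.random.default_rng(seed)
    soc = np.r_[["non-industrial"] * (n // 4), ["industrial"] * (n - n // 4)]
    age = rng.uniform(18, 70, n)
    sex = rng.choice(["male", "female"], n)
    age_z = (age - age.mean()) / age.std()
    cfi = (
        0.70 + beta_soc * (soc == "industrial") + beta_age * age_z
        - 0.01 * (sex == "male") + rng.normal(0, 0.07, n)
    )
    return pd.DataFrame(
        {"subject_id": np.arange(n), "population": soc, "society_scale": soc,
         "cfi": np.clip(cfi, 0, 1), "age": age, "sex": sex}
    )


def test_cfi_model_detects_society_effect():
    fit = fit_cfi_model(_cfi_table(seed=1), mcmc=McmcConfig(seed=1))
    s = fit.summaries["society_industrial"]
    assert s.pct_negative > 95.0
    assert s.support_label == "strong"
    # contrast is the industrial offset itself for this parameterization
    c = group_contrast(fit)
    assert c.estimate == pytest.approx(s.estimate)


def test_cfi_model_null_age_effect_covers_zero():
    fit = fit_cfi_model(_cfi_table(beta_age=0.0, seed=2), mcmc=FAST)
    lo, hi = fit.summaries["age_z"].ci95
    assert lo < 0.0 < hi


def test_cfi_model_constant_outcome_errors():
    df = _cfi_table(seed=0)
    df["cfi"] = 0.5
    with pytest.raises(ValueError, match="constant"):
        fit_cfi_model(df, mcmc=FAST)


def test_cfi_prior_set_values():
    p = PriorSet.cfi()
    assert (p.intercept_mean, p.intercept_sd) == (0.58, 0.1)


# ------------------------------------------------------ model comparison

def test_identical_formulas_have_zero_elpd_difference():
    df = generate_study_table(StudyGenParams(seed=5))
    cmp = compare_models(
        df,
        [("society_scale", "age", "pct_male"), ("society_scale", "age", "pct_male")],
        mcmc=FAST,
    )
    a, b = cmp.model_names
    diff, se = cmp.difference(a, b)
    assert diff == pytest.approx(0.0, abs=1e-9)


def test_society_model_outranks_null_when_effect_is_strong():
    g = StudyGenParams(true_beta_society=-2.5, country_sd=0.3, seed=6)
    df = generate_study_table(g)
    cmp = compare_models(
        df, [("society_scale", "age", "pct_male"), ("age", "pct_male")],
        mcmc=FAST,
    )
    full = cmp.model_names[0]
    assert cmp.ranking()[0] == full
    # pairwise differences are antisymmetric
    a, b = cmp.model_names
    assert cmp.difference(a, b)[0] == pytest.approx(-cmp.difference(b, a)[0])


def test_null_simulation_elpd_difference_is_small():
    g = StudyGenParams(true_beta_society=0.0, seed=7)
    df = generate_study_table(g)
    cmp = compare_models(
        df, [("society_scale", "age", "pct_male"), ("age", "pct_male")],
        mcmc=FAST,
    )
    a, b = cmp.model_names
    diff, se = cmp.difference(a, b)
    assert abs(diff) < 2 * max(se, 1.0)


def test_exact_loo_agrees_with_psis_on_small_table():
    g = StudyGenParams(n_studies=12, n_countries=4,
                       n_nonindustrial_studies=4, n_nonindustrial_countries=2,
                       seed=8)
    df = generate_study_table(g)
    tiny = McmcConfig(n_chains=2, n_walkers=24, n_warmup=400, n_keep=100,
                      seed=0, check_convergence=False)
    formulas = [("society_scale",), ("society_scale", "age")]
    psis = compare_models(df, formulas, mcmc=tiny, method="psis")
    exact = compare_models(df, formulas, mcmc=tiny, method="exact")
    for name in psis.model_names:
        assert psis.elpd[name] == pytest.approx(exact.elpd[name], abs=2.0)
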