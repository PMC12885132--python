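"""Synthetic-cohort generator tests: determinism, the Markov exposure
process, covariate marginals, outcome assignment and missingness injection."""

from dataclasses import replace
from datetime import date

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

import statsmodels.api as sm

from smokeptb.simulate import (
    CohortConfig,
    COVARIATE_MARGINALS,
    ExposureProcessParams,
    HazardParams,
    MissingnessRule,
    ParameterError,
    assign_outcomes,
    default_baseline_logit,
    inject_missingness,
    simulate_cohort,
    simulate_pregnancies,
    simulate_tract_series,
)
from conftest import quick_config


# ---------------------------------------------------------------------------
# exposure process
# ---------------------------------------------------------------------------

def test_no_entry_means_all_zero_series():
    params = ExposureProcessParams(p_enter_smoke=0.0)
    s = simulate_tract_series(
        params, {"tract_id": "t0", "region": "West"}, (date(2018, 1, 1), date(2019, 12, 31)), 7
    )
    assert np.all(s.values == 0.0)


def test_series_deterministic_under_seed():
    params = ExposureProcessParams()
    tract = {"tract_id": "t0", "region": "Midwest", "frailty": 1.3}
    window = (date(2017, 1, 1), date(2018, 12, 31))
    a = simulate_tract_series(params, tract, window, 99)
    b = simulate_tract_series(params, tract, window, 99)
    assert np.array_equal(a.values, b.values)
    c = simulate_tract_series(params, tract, window, 100)
    assert not np.array_equal(a.values, c.values)


def test_non_smoke_days_exactly_zero_and_values_nonnegative():
    s = simulate_tract_series(
        ExposureProcessParams(),
        {"tract_id": "t0", "region": "West"},
        (date(2015, 1, 1), date(2018, 12, 31)), 3,
    )
    v = s.values
    assert np.all(v >= 0)
    assert np.all((v == 0) | (v > 0))  # zeros are exact, no epsilon smear
    assert (v == 0).any() and (v > 0).any()


def test_stationary_smoke_fraction_matches_closed_form():
    """Plain two-state chain (no persistence modulation, no seasonality, no
    frailty): empirical smoke-day fraction ~ p/(p+1-q)."""
    params = ExposureProcessParams(
        p_enter_smoke=0.05, p_stay_smoke=0.6,
        stay_intensity_slope=0.0, stay_intensity_slope2=0.0, stay_age_decay=0.0,
        seasonal_amplitude=0.0, tract_rate_shape=1e9,
        region_scalers={"West": (1.0, 1.0)},
    )
    expected = params.stationary_smoke_fraction
    assert expected == pytest.approx(0.05 / (0.05 + 0.4))
    days = 0
    total = 0
    for seed in range(6):
        s = simulate_tract_series(
            params, {"tract_id": f"t{seed}", "region": "West", "frailty": 1.0},
            (date(2006, 1, 1), date(2020, 12, 31)), seed,
        )
        days += (s.values > 0).sum()
        total += len(s.values)
    frac = days / total  # ~33k tract-days
    assert frac == pytest.approx(expected, rel=0.05)


def test_invalid_probability_rejected():
    with pytest.raises(ParameterError):
        ExposureProcessParams(p_enter_smoke=1.5)
    with pytest.raises(ParameterError):
        ExposureProcessParams(intensity_log_sd=0.0)


# ---------------------------------------------------------------------------
# pregnancies and covariates
# ---------------------------------------------------------------------------

def test_no_moves_means_single_interval():
    cfg = quick_config(n=300, move_fraction=0.0)
    _, residence, _, _ = simulate_pregnancies(cfg, ExposureProcessParams())
    counts = residence.groupby("pregnancy_id").size()
    assert (counts == 1).all()


def test_move_fraction_gives_two_intervals():
    cfg = quick_config(n=400, move_fraction=0.5, seed=7)
    _, residence, _, _ = simulate_pregnancies(cfg, ExposureProcessParams())
    counts = residence.groupby("pregnancy_id").size()
    assert counts.isin([1, 2]).all()
    assert abs((counts == 2).mean() - 0.5) < 0.08


def test_mean_age_matches_cohort_marginal():
    cfg = quick_config(n=20_000, seed=3)
    preg, _, _, _ = simulate_pregnancies(cfg, ExposureProcessParams())
    assert preg["age"].mean() == pytest.approx(30.6, abs=0.2)


def test_covariate_marginals_match_independent_samplers(rng):
    """Generated covariates agree with naive re-implementations of each
    marginal sampler (KS for continuous, max proportion gap for categorical)."""
    cfg = quick_config(n=20_000, seed=11)
    preg, _, _, _ = simulate_pregnancies(cfg, ExposureProcessParams())
    m = COVARIATE_MARGINALS
    # continuous: age, bmi via the same truncation rule, fresh rng
    ref_age = np.clip(rng.normal(m["age_mean"], m["age_sd"], 20_000), 14.0, 50.0)
    assert stats.ks_2samp(preg["age"], ref_age).pvalue > 0.01
    ref_bmi = np.clip(rng.normal(m["bmi_mean"], m["bmi_sd"], 20_000), 15.0, 60.0)
    assert stats.ks_2samp(preg["bmi"], ref_bmi).pvalue > 0.01
    # categorical: observed shares within sampling error of the spec'd probs
    for col, probs in [
        ("race", m["race_probs"]),
        ("education", m["education_probs"]),
        ("parity", m["parity_probs"]),
    ]:
        got = preg[col].value_counts(normalize=True)
        for level, p in probs.items():
            assert got[level] == pytest.approx(p, abs=0.015)
    assert preg["hispanic"].mean() == pytest.approx(m["p_hispanic"], abs=0.01)
    assert (preg["infant_sex"] == "female").mean() == pytest.approx(m["p_female"], abs=0.015)


def test_conceptions_inside_window(small_cohort):
    preg = small_cohort.pregnancies
    c = pd.to_datetime(pd.Series(list(preg["conception_date"])))
    assert c.min().date() >= small_cohort.config.conception_start
    assert c.max().date() <= small_cohort.config.conception_end


def test_bad_cohort_config_rejected():
    with pytest.raises(ParameterError):
        CohortConfig(n_pregnancies=0)
    with pytest.raises(ParameterError):
        CohortConfig(conception_start=date(2020, 1, 1), conception_end=date(2019, 1, 1))


# ---------------------------------------------------------------------------
# outcome assignment
# ---------------------------------------------------------------------------

def _dummy_cumexp(n, value=0.0):
    return np.full((n, 15), value)


def _toy_pregnancies(n, rng, n_sites=4):
    return pd.DataFrame(
        {
            "pregnancy_id": [f"P{i}" for i in range(n)],
            "site_id": rng.choice([f"S{k}" for k in range(n_sites)], n),
            "age": np.full(n, 30.6),
            "infant_sex": "male",
            "race": "White",
            "hispanic": 0,
            "poverty_rate": 14.7,
            "bmi": 26.8,
            "tobacco": 0,
        }
    )


def test_zero_hazard_gives_zero_preterm(rng, null_hazard):
    hz = replace(null_hazard, baseline_logit=np.full(15, -745.0))
    preg = _toy_pregnancies(2000, rng)
    out = assign_outcomes(preg, _dummy_cumexp(2000), hz, seed=5)
    assert out["preterm"].sum() == 0
    assert (out["ga_days"] >= 259).all()


def test_marginal_preterm_matches_survival_product(rng, null_hazard):
    """With no exposure/covariate/site effects the preterm fraction equals
    1 - prod_w (1 - h_w), the closed-form complement of surviving weeks 22-36."""
    h = expit(default_baseline_logit())
    expected = 1.0 - np.prod(1.0 - h)
    n = 60_000
    preg = _toy_pregnancies(n, rng)
    out = assign_outcomes(preg, _dummy_cumexp(n), null_hazard, seed=6)
    mc_sd = np.sqrt(expected * (1 - expected) / n)
    assert out["preterm"].mean() == pytest.approx(expected, abs=4 * mc_sd)


def test_positive_beta_raises_rate_in_top_quartile(rng, null_hazard):
    n = 40_000
    preg = _toy_pregnancies(n, rng)
    exposure = rng.gamma(2.0, 2.0, n)
    cumexp = np.tile(exposure[:, None], (1, 15))
    hz = replace(null_hazard, beta_exposure=np.log(1.10))
    out = assign_outcomes(preg, cumexp, hz, seed=7)
    q1, q3 = np.quantile(exposure, [0.25, 0.75])
    low = out["preterm"][exposure <= q1].mean()
    high = out["preterm"][exposure >= q3].mean()
    assert high > low


def test_missing_cumexp_is_data_error(rng, null_hazard):
    from smokeptb.simulate import DataError

    preg = _toy_pregnancies(10, rng)
    bad = _dummy_cumexp(10)
    bad[3, 7] = np.nan
    with pytest.raises(DataError):
        assign_outcomes(preg, bad, null_hazard, seed=1)


def test_term_ga_distribution_respected(rng, null_hazard):
    hz = replace(null_hazard, baseline_logit=np.full(15, -745.0))
    out = assign_outcomes(_toy_pregnancies(20_000, rng), _dummy_cumexp(20_000), hz, seed=9)
    weeks = out["ga_days"] // 7
    dist = weeks.value_counts(normalize=True)
    for w, p in null_hazard.term_ga_distribution.items():
        assert dist.get(w, 0.0) == pytest.approx(p, abs=0.01)


def test_severity_band_split():
    """Default hazard splits preterm births roughly 1.0 : 0.9 : 6.4 across
    <32, 32-33 and 34-36 completed weeks."""
    c = simulate_cohort(quick_config(n=12_000, n_sites=10, seed=31))
    ga = c.pregnancies["ga_days"]
    f_early = (ga < 224).mean()
    f_mod = ((ga >= 224) & (ga < 238)).mean()
    f_late = ((ga >= 238) & (ga < 259)).mean()
    assert f_early == pytest.approx(0.010, rel=0.35)
    assert f_mod == pytest.approx(0.009, rel=0.35)
    assert f_late == pytest.approx(0.064, rel=0.20)


# ---------------------------------------------------------------------------
# whole-cohort determinism and null linkage
# ---------------------------------------------------------------------------

def test_cohort_byte_identical_under_seed():
    a = simulate_cohort(quick_config(n=250, seed=8))
    b = simulate_cohort(quick_config(n=250, seed=8))
    pd.testing.assert_frame_equal(a.pregnancies, b.pregnancies)
    pd.testing.assert_frame_equal(a.metrics, b.metrics)
    assert np.array_equal(a.exposure_matrix, b.exposure_matrix, equal_nan=True)
    c = simulate_cohort(quick_config(n=250, seed=9))
    assert not a.pregnancies["ga_days"].equals(c.pregnancies["ga_days"])


def test_null_linkage_pvalues_uniform(null_hazard):
    """beta_exposure=0: the p-value of fixed-window smoke days in a preterm
    logistic is uniform over replicate cohorts (KS against U(0,1)).

    The exposure window is fixed at conception..week 22 (shared by every
    pregnancy at risk): total smoke days over the whole pregnancy would be
    mechanically shorter for preterm births and the regression would not be
    null even with beta_exposure = 0."""
    pvals = []
    for rep in range(50):
        c = simulate_cohort(
            quick_config(n=400, n_sites=4, n_tracts_per_site=2, seed=1000 + rep),
            hazard=null_hazard,
        )
        w22 = c.cumulative[c.cumulative["week"] == 22][["pregnancy_id", "cum_days_gt0"]]
        df = c.pregnancies.merge(w22, on="pregnancy_id")
        X = sm.add_constant(df["cum_days_gt0"].to_numpy(float))
        res = sm.Logit(df["preterm"].to_numpy(float), X).fit(disp=0)
        pvals.append(res.pvalues[1])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# missingness injection
# ---------------------------------------------------------------------------

def test_missingness_rate_zero_is_identity(small_cohort):
    rules = (MissingnessRule("bmi", "MCAR", 0.0),)
    out = inject_missingness(small_cohort.pregnancies, rules, seed=3)
    pd.testing.assert_frame_equal(out, small_cohort.pregnancies)


def test_mcar_rate_recovered(small_cohort):
    rules = (MissingnessRule("bmi", "MCAR", 0.2),)
    out = inject_missingness(small_cohort.pregnancies, rules, seed=4)
    n = len(out)
    rate = out["bmi"].isna().mean()
    assert rate == pytest.approx(0.2, abs=3 * np.sqrt(0.2 * 0.8 / n))
    # untouched cells identical
    obs = out["bmi"].notna()
    assert np.array_equal(out.loc[obs, "bmi"], small_cohort.pregnancies.loc[obs, "bmi"])


def test_mar_rates_differ_by_stratum(small_cohort):
    rates = {"hs_or_less": 0.4, "some_college": 0.2, "bachelor": 0.1, "postgraduate": 0.05}
    rules = (
        MissingnessRule("tobacco", "MAR", depends_on="education", rate_by_level=rates),
    )
    out = inject_missingness(small_cohort.pregnancies, rules, seed=5)
    got = out.groupby("education")["tobacco"].apply(lambda s: s.isna().mean())
    for lev, r in rates.items():
        n_lev = (small_cohort.pregnancies["education"] == lev).sum()
        assert got[lev] == pytest.approx(r, abs=4 * np.sqrt(r * (1 - r) / n_lev) + 0.02)


def test_mar_on_masked_conditioner_rejected(small_cohort):
    rules = (
        MissingnessRule("education", "MCAR", 0.2),
        MissingnessRule("tobacco", "MAR", depends_on="education",
                        rate_by_level={"hs_or_less": 0.3, "some_college": 0.3,
                                       "bachelor": 0.3, "postgraduate": 0.3}),
    )
    with pytest.raises(ParameterError):
        inject_missingness(small_cohort.pregnancies, rules, seed=6)


def test_outcome_and_exposure_never_masked(small_cohort):
    with pytest.raises(ParameterError):
        inject_missingness(
            small_cohort.pregnancies, (MissingnessRule("ga_days", "MCAR", 0.1),), seed=7
        )
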