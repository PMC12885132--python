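"""Model-layer tests: spline bases, pooled logistic vs an IRLS oracle, the
mixed-effects engine, week-window models, the gestational-age model, effect
modification and the sensitivity suite."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from smokeptb.cohort import person_period_expand
from smokeptb.glmm import FitError, fit_logistic_mixed
from smokeptb.models import (
    ModelSpec,
    build_design,
    effect_modification,
    fit_gestational_age_linear,
    fit_pooled_logistic,
    fit_week_window_models,
    poverty_tertiles,
    sensitivity_suite,
)
from smokeptb.simulate import HazardParams, simulate_cohort
from smokeptb.splines import natural_cubic_basis, spline_basis, thin_plate_basis
from conftest import quick_config


# ---------------------------------------------------------------------------
# splines
# ---------------------------------------------------------------------------

def test_spline_column_counts(rng):
    x = rng.normal(size=300)
    for df in (1, 2, 3, 5):
        assert natural_cubic_basis(x, df).shape == (300, df)
    xy = rng.normal(size=(300, 2))
    for df in (3, 5, 10):
        assert thin_plate_basis(xy, df).shape == (300, df)
    assert spline_basis(x, 3).shape[1] == 3
    assert spline_basis(xy, 10, kind="thin_plate_2d").shape[1] == 10


def test_spline_df_errors(rng):
    with pytest.raises(ValueError):
        natural_cubic_basis(np.array([1.0, 2.0, 1.0, 2.0]), 3)
    with pytest.raises(ValueError):
        thin_plate_basis(rng.normal(size=(50, 3)), 5)
    with pytest.raises(ValueError):
        spline_basis(rng.normal(size=10), 2, kind="nope")


def _fitted(X, y):
    Xc = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    return Xc @ beta


def test_natural_cubic_contains_linear_trend(rng):
    x = rng.normal(size=400)
    y = 2.0 + 3.0 * x
    assert np.allclose(_fitted(natural_cubic_basis(x, 3), y), y, atol=1e-8)


def test_thin_plate_translation_invariance(rng):
    xy = rng.uniform(-3, 3, size=(400, 2))
    y = np.sin(xy[:, 0]) + 0.5 * xy[:, 1] + rng.normal(0, 0.1, 400)
    f0 = _fitted(thin_plate_basis(xy, 8), y)
    f1 = _fitted(thin_plate_basis(xy + np.array([120.0, -45.0]), 8), y)
    assert np.allclose(f0, f1, atol=1e-6)


def test_thin_plate_contains_linear_trend(rng):
    xy = rng.uniform(0, 10, size=(300, 2))
    y = 1.0 + 2.0 * xy[:, 0] - 3.0 * xy[:, 1]
    assert np.allclose(_fitted(thin_plate_basis(xy, 6), y), y, atol=1e-7)


# ---------------------------------------------------------------------------
# pooled logistic vs IRLS oracle
# ---------------------------------------------------------------------------

def irls_oracle(X, y, tol=1e-12, max_iter=200):
    """Plain Newton/IRLS logistic MLE, independent of the package path."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = expit(X @ beta)
        W = p * (1 - p)
        H = (X.T * W) @ X
        step = np.linalg.solve(H, X.T @ (y - p))
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


@pytest.fixture(scope="module")
def null_cluster_cohort(null_hazard):
    # a flat weekly baseline keeps events in every gestational week, so the
    # week-indicator MLE is interior and oracle comparisons are exact
    flat = np.full(15, np.log(0.004 / 0.996))
    hz = replace(null_hazard, beta_exposure=np.log(1.03),
                 exposure_metric="cum_days_gt0", baseline_logit=flat)
    return simulate_cohort(quick_config(n=2500, n_sites=5, seed=77), hazard=hz)


def test_pooled_logistic_matches_irls_oracle(null_cluster_cohort):
    c = null_cluster_cohort
    table = person_period_expand(c.pregnancies, c.cumulative)
    spec = ModelSpec(exposure_term="cum_days_gt0", covariate_set="none", cluster_mode="none")
    fit = fit_pooled_logistic(table, spec)
    assert fit.converged
    X = build_design(table, spec, week_indicators=True).to_numpy()
    beta = irls_oracle(X, table["event"].to_numpy(float))
    assert np.allclose(fit.params.to_numpy(), beta, atol=1e-6)


def test_pooled_equals_single_logistic_when_unclustered(null_cluster_cohort):
    """Random-intercept machinery collapses to the plain fit when the
    generator has no site effects (sigma-hat ~ 0)."""
    c = null_cluster_cohort
    table = person_period_expand(c.pregnancies, c.cumulative)
    spec = ModelSpec(exposure_term="cum_days_gt0", covariate_set="none")
    plain = fit_pooled_logistic(table, replace(spec, cluster_mode="none"))
    mixed = fit_pooled_logistic(table, spec)
    assert mixed.converged
    # 5 clusters resolve sigma only coarsely; the estimate should be small
    # and the exposure coefficient a small fraction of its SE from the
    # unclustered fit (exact equality holds only as sigma-hat -> 0)
    assert mixed.variance_components["site_intercept_sd"] < 0.2
    assert abs(mixed.exposure_coef - plain.exposure_coef) < 0.25 * plain.exposure_se


def test_agq_close_to_laplace(null_cluster_cohort):
    c = null_cluster_cohort
    table = person_period_expand(c.pregnancies, c.cumulative)
    spec = ModelSpec(exposure_term="cum_days_gt0", covariate_set="none")
    agq = fit_pooled_logistic(table, spec)
    lap = fit_pooled_logistic(table, replace(spec, method="laplace"))
    assert agq.exposure_coef == pytest.approx(lap.exposure_coef, abs=5e-3)


def test_fixed_effect_reference_level_irrelevant(null_cluster_cohort):
    """Relabelling the race reference level leaves the exposure estimate
    unchanged (any full-rank parameterisation is equivalent)."""
    c = null_cluster_cohort
    births = c.pregnancies.copy()
    table = person_period_expand(births, c.cumulative)
    spec = ModelSpec(exposure_term="cum_days_gt0", covariate_set="model1", cluster_mode="none")
    f0 = fit_pooled_logistic(table, spec)
    relabel = {"White": "MultiOther", "MultiOther": "White"}
    table2 = table.assign(race=table["race"].map(lambda r: relabel.get(r, r)))
    f1 = fit_pooled_logistic(table2, spec)
    assert f0.exposure_coef == pytest.approx(f1.exposure_coef, abs=1e-7)


def test_zero_events_is_error(null_cluster_cohort):
    c = null_cluster_cohort
    table = person_period_expand(c.pregnancies, c.cumulative)
    table = table[table["event"] == 0]
    with pytest.raises((FitError, Exception)):
        fit_pooled_logistic(
            table, ModelSpec(exposure_term="cum_days_gt0", covariate_set="none")
        )


# ---------------------------------------------------------------------------
# mixed engine sanity on data with real clustering
# ---------------------------------------------------------------------------

def test_mixed_engine_recovers_sigma(rng):
    n_g, n_per = 25, 200
    g = np.repeat(np.arange(n_g), n_per)
    x = rng.normal(size=n_g * n_per)
    b = rng.normal(0, 0.6, n_g)
    y = (rng.random(n_g * n_per) < expit(-1.0 + 0.5 * x + b[g])).astype(float)
    X = np.column_stack([np.ones_like(x), x])
    r = fit_logistic_mixed(X, y, g, n_nodes=7)
    assert r.converged
    assert r.beta[1] == pytest.approx(0.5, abs=0.1)
    assert r.sigma == pytest.approx(0.6, abs=0.25)
    assert np.isfinite(r.se).all()


# ---------------------------------------------------------------------------
# week-window models
# ---------------------------------------------------------------------------

def test_week_window_contracts(null_cluster_cohort):
    c = null_cluster_cohort
    births = c.pregnancies.merge(c.metrics, on="pregnancy_id")
    spec = ModelSpec(covariate_set="none", cluster_mode="none")
    with pytest.raises(ValueError):
        fit_week_window_models(births, c.weekly, spec, weeks=[36])
    fits = fit_week_window_models(births, c.weekly, spec, weeks=[0, 10, 30])
    assert set(fits) == {0, 10, 30}
    # week-30 model only includes births delivering after week 31
    assert fits[30].n_pregnancies == int((births["ga_days"] > 7 * 31).sum())
    for f in fits.values():
        assert f.converged


def test_week_window_zero_variance_flagged(null_cluster_cohort):
    c = null_cluster_cohort
    births = c.pregnancies.merge(c.metrics, on="pregnancy_id")
    weekly = c.weekly.copy()
    weekly.loc[weekly["week"] == 5, "days_gt0"] = 0
    spec = ModelSpec(covariate_set="none", cluster_mode="none")
    fits = fit_week_window_models(births, weekly, spec, weeks=[5])
    assert not fits[5].converged and fits[5].method == "skipped"


# ---------------------------------------------------------------------------
# gestational-age linear model
# ---------------------------------------------------------------------------

def _ga_births(rng, n=4000, slope=-0.5, sigma_site=2.0):
    sites = rng.integers(0, 8, n)
    b = rng.normal(0, sigma_site, 8)
    exposure = rng.gamma(2.0, 2.0, n)
    ga = 278 + slope * exposure + b[sites] + rng.normal(0, 9, n)
    return pd.DataFrame(
        {
            "pregnancy_id": [f"P{i}" for i in range(n)],
            "site_id": [f"S{s}" for s in sites],
            "ga_days": ga.astype(int),
            "exp_to_32w": exposure,
        }
    )


def test_ga_linear_recovers_slope(rng):
    births = _ga_births(rng)
    spec = ModelSpec(exposure_term="exp_to_32w", covariate_set="none")
    fit = fit_gestational_age_linear(births, spec, "exp_to_32w")
    assert fit.converged and fit.family == "linear"
    assert fit.exposure_coef == pytest.approx(-0.5, abs=0.12)


def test_ga_linear_excludes_early_births(rng):
    births = _ga_births(rng, n=500)
    births.loc[0, "ga_days"] = 30 * 7  # a 30-week birth
    spec = ModelSpec(exposure_term="exp_to_32w", covariate_set="none", cluster_mode="none")
    fit = fit_gestational_age_linear(births, spec, "exp_to_32w")
    assert fit.n_pregnancies == int((births["ga_days"] >= 224).sum())


def test_ga_linear_null_covers_zero(rng):
    births = _ga_births(rng, n=3000, slope=0.0)
    spec = ModelSpec(exposure_term="exp_to_32w", covariate_set="none", cluster_mode="none")
    fit = fit_gestational_age_linear(births, spec, "exp_to_32w")
    assert abs(fit.exposure_coef) < 3 * fit.exposure_se


# ---------------------------------------------------------------------------
# effect modification
# ---------------------------------------------------------------------------

def test_poverty_tertiles_balanced(rng):
    v = pd.Series(rng.gamma(1.3, 11.0, 2000))
    t = poverty_tertiles(v)
    counts = t.value_counts()
    assert counts.max() - counts.min() <= 2


def test_effect_modification_contracts(null_cluster_cohort):
    c = null_cluster_cohort
    table = person_period_expand(c.pregnancies, c.cumulative)
    spec = ModelSpec(exposure_term="cum_days_gt0", covariate_set="none", cluster_mode="none")
    res = effect_modification(table, spec, "infant_sex")
    assert set(res.stratified) == {"female", "male"}
    assert res.interaction_df == 1
    assert 0.0 <= res.interaction_p <= 1.0
    # 1-df Wald chi-square equals the squared-z test of the product term
    term = f"cum_days_gt0:infant_sex[male]"
    z = res.pooled.params[term] / res.pooled.se[term]
    assert res.interaction_p == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-6)
    with pytest.raises(ValueError):
        effect_modification(table.assign(infant_sex="male"), spec, "infant_sex")


def test_effect_modification_categorical_df(null_cluster_cohort):
    c = null_cluster_cohort
    table = person_period_expand(c.pregnancies, c.cumulative)
    spec = ModelSpec(exposure_term="cum_days_gt0", covariate_set="none", cluster_mode="none")
    res = effect_modification(table, spec, "poverty_tertile")
    assert res.interaction_df == 2
    assert set(res.stratified) == {"T1", "T2", "T3"}


# ---------------------------------------------------------------------------
# sensitivity suite
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def sensitivity_inputs(null_hazard):
    hz = replace(null_hazard, beta_exposure=np.log(1.03), exposure_metric="cum_days_gt0")
    c = simulate_cohort(
        quick_config(n=1500, n_sites=5, seed=55, include_confounders=True), hazard=hz
    )
    births = c.pregnancies.merge(c.metrics, on="pregnancy_id")
    mat, valid = c.exposure_matrix, ~np.isnan(c.exposure_matrix)
    filled = np.where(valid, mat, 0.0)
    for name, (a, b) in {"t1": (0, 91), "t2": (91, 189), "t3": (189, mat.shape[1])}.items():
        n = valid[:, a:b].sum(axis=1)
        births[f"{name}_mean"] = np.where(n > 0, filled[:, a:b].sum(axis=1) / np.maximum(n, 1), 0.0)
    table = person_period_expand(births, c.cumulative)
    return table, births


def test_sensitivity_suite_variants(sensitivity_inputs):
    table, births = sensitivity_inputs
    spec = ModelSpec(exposure_term="cum_days_gt0", covariate_set="none")
    out = sensitivity_suite(table, births, spec)
    assert set(out) == {"trimester_exposure", "confounder_adjusted",
                        "site_fixed_effects", "random_slope", "complete_case"}
    # variant 1 returns the three trimester coefficients
    tri = out["trimester_exposure"]
    assert {"t1_mean", "t2_mean", "t3_mean"} <= set(tri.params.index)
    # variant 5 on complete data is identical to the primary fit
    primary = fit_pooled_logistic(table, spec)
    assert np.allclose(
        out["complete_case"].params.to_numpy(), primary.params.to_numpy(), atol=1e-10
    )
    # variant 3 on sigma_site=0 data stays within one SE of the primary fit
    fe = out["site_fixed_effects"]
    assert abs(fe.exposure_coef - primary.exposure_coef) < primary.exposure_se
    assert out["random_slope"].variance_components["site_slope_sd"] >= 0


def test_sensitivity_requires_confounder_series(null_cluster_cohort):
    c = null_cluster_cohort
    births = c.pregnancies.merge(c.metrics, on="pregnancy_id")
    births["t1_mean"] = births["t2_mean"] = births["t3_mean"] = 0.5
    table = person_period_expand(births, c.cumulative)
    spec = ModelSpec(exposure_term="cum_days_gt0", covariate_set="none")
    with pytest.raises(ValueError):
        sensitivity_suite(table, births, spec)


# ---------------------------------------------------------------------------
# monotone exposure-response recovery
# ---------------------------------------------------------------------------

def test_intensity_gradient_recovered(null_hazard):
    """When the true hazard loads on high-intensity smoke days, fitted ORs
    rise with the smoke-day intensity threshold in most replicates."""
    hits = 0
    reps = 6
    for rep in range(reps):
        hz = replace(null_hazard, beta_exposure=np.log(1.10), exposure_metric="cum_days_ge10")
        c = simulate_cohort(quick_config(n=4000, n_sites=5, seed=300 + rep), hazard=hz)
        table = person_period_expand(c.pregnancies, c.cumulative)
        ors = []
        for term in ("cum_days_gt0", "cum_days_ge2p5", "cum_days_ge5", "cum_days_ge10"):
            spec = ModelSpec(exposure_term=term, covariate_set="none", cluster_mode="none")
            ors.append(fit_pooled_logistic(table, spec).exposure_or)
        if all(a < b for a, b in zip(ors, ors[1:])):
            hits += 1
    assert hits > reps / 2
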