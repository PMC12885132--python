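"""Statistical models: pooled logistic regression for preterm birth, weekly
critical-window models, the gestational-age linear model, effect modification
and the sensitivity suite.

The primary analysis is discrete-time survival via pooled logistic
regression: the person-period table (one row per pregnancy × at-risk
gestational week 22–36) is fitted with gestational-week indicator fixed
effects, a time-updated cumulative exposure term, the chosen covariate set
and a study-site random intercept, giving the conditional odds ratio of
delivery per unit of cumulative exposure given continuation to the week's
start.

Covariate sets:

* ``model1`` — infant sex, age at delivery (natural cubic spline, 3 df),
  race, Hispanic ethnicity, census-tract poverty rate, season of conception,
  birth year (spline, 4 df), and a 2-d thin-plate spatial smooth (10 df);
* ``model2`` — model 1 plus parity, prepregnancy BMI, tobacco use, alcohol
  consumption, gestational-age determination method and education;
* ``none`` — intercept (+ week indicators) and exposure only, for simulation
  studies whose generator has no covariate effects.

Reference levels: race White, season winter, parity 0; site cluster handling
is selectable (random intercept via adaptive quadrature — the default,
Laplace, site fixed effects, or none).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .glmm import FitError, fit_logistic_mixed, fit_logistic_mixed_slope
from .splines import natural_cubic_basis, thin_plate_basis

Z95 = 1.959963984540054

RACE_LEVELS = ("White", "Black", "AsianNHPI", "AIAN", "MultiOther")
SEASON_LEVELS = ("winter", "spring", "summer", "autumn")
EDUCATION_LEVELS = ("hs_or_less", "some_college", "bachelor", "postgraduate")


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: exposure term, adjustment set and cluster handling."""

    exposure_term: str = "cum_mean"
    covariate_set: str = "model1"          # model1 | model2 | none
    cluster: str = "site_id"
    cluster_mode: str = "random_intercept" # random_intercept | random_slope | fixed_effects | none
    spline_df: Mapping[str, int] = field(
        default_factory=lambda: {"age": 3, "birth_year": 4, "spatial": 10}
    )
    method: str = "agq"                    # agq | laplace (random_intercept only)
    n_nodes: int = 7
    adjust_temperature: bool = False
    adjust_ambient_pm: bool = False
    extra_covariates: tuple[str, ...] = () # additional plain columns for the design

    def __post_init__(self) -> None:
        if self.covariate_set not in ("model1", "model2", "none"):
            raise ValueError(f"unknown covariate set {self.covariate_set!r}")
        if self.cluster_mode not in ("random_intercept", "random_slope", "fixed_effects", "none"):
            raise ValueError(f"unknown cluster mode {self.cluster_mode!r}")
        for k, v in self.spline_df.items():
            if v < 1:
                raise ValueError(f"spline df for {k} must be positive")


@dataclass
class FitResult:
    """Coefficients, Wald 95% CIs on the link scale, and fit metadata."""

    params: pd.Series
    se: pd.Series
    exposure_term: str
    loglik: float
    converged: bool
    n_rows: int
    n_pregnancies: int
    n_events: int
    variance_components: dict = field(default_factory=dict)
    cov: pd.DataFrame | None = None
    outcome: str = "event"
    family: str = "logistic"
    method: str = ""
    t_df: pd.Series | None = None  # per-coefficient t dof (Rubin-pooled fits)

    def _ci_mult(self) -> pd.Series | float:
        if self.t_df is None:
            return Z95
        return pd.Series(stats.t.ppf(0.975, np.maximum(self.t_df, 1.0)), index=self.params.index)

    @property
    def ci_low(self) -> pd.Series:
        return self.params - self._ci_mult() * self.se

    @property
    def ci_high(self) -> pd.Series:
        return self.params + self._ci_mult() * self.se

    @property
    def exposure_coef(self) -> float:
        return float(self.params[self.exposure_term])

    @property
    def exposure_se(self) -> float:
        return float(self.se[self.exposure_term])

    @property
    def exposure_or(self) -> float:
        return float(np.exp(self.exposure_coef))

    @property
    def exposure_ci(self) -> tuple[float, float]:
        return (
            float(np.exp(self.exposure_coef - Z95 * self.exposure_se)),
            float(np.exp(self.exposure_coef + Z95 * self.exposure_se)),
        )

    def wald_p(self, term: str | None = None) -> float:
        term = term or self.exposure_term
        z = self.params[term] / self.se[term]
        return float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# design matrix assembly
# ---------------------------------------------------------------------------

def _dummies(values: pd.Series, levels: Sequence, prefix: str) -> pd.DataFrame:
    cols = {}
    for lev in levels[1:]:  # first level is the reference
        cols[f"{prefix}[{lev}]"] = (values == lev).astype(float).to_numpy()
    return pd.DataFrame(cols, index=values.index)


def build_design(
    df: pd.DataFrame,
    spec: ModelSpec,
    exposure_term: str | None = "__from_spec__",
    week_indicators: bool = False,
    extra_columns: Sequence[str] = (),
) -> pd.DataFrame:
    """Assemble the fixed-effects design matrix (including intercept).

    ``exposure_term=None`` omits the exposure column entirely."""
    parts = [pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)]
    if week_indicators:
        weeks = sorted(df["gestational_week"].unique())
        parts.append(_dummies(df["gestational_week"], weeks, "week"))
    if exposure_term == "__from_spec__":
        exposure_term = spec.exposure_term
    if exposure_term:
        parts.append(df[[exposure_term]].astype(float))

    if spec.covariate_set in ("model1", "model2"):
        parts.append(_dummies(df["infant_sex"], ("male", "female"), "sex"))
        # spline dfs are capped by the distinct values actually present, so
        # small strata/subsamples stay estimable
        age = natural_cubic_basis(
            df["age"].to_numpy(float),
            min(spec.spline_df["age"], df["age"].nunique() - 1),
        )
        parts.append(pd.DataFrame(
            age, index=df.index,
            columns=[f"age_ns{i+1}" for i in range(age.shape[1])],
        ))
        parts.append(_dummies(df["race"], RACE_LEVELS, "race"))
        parts.append(df[["hispanic"]].astype(float))
        parts.append(df[["poverty_rate"]].astype(float))
        parts.append(_dummies(df["season_conception"], SEASON_LEVELS, "season"))
        n_years = df["birth_year"].nunique()
        if n_years > 1:
            by = natural_cubic_basis(
                df["birth_year"].to_numpy(float),
                min(spec.spline_df["birth_year"], n_years - 1),
            )
            parts.append(pd.DataFrame(
                by, index=df.index,
                columns=[f"birth_year_ns{i+1}" for i in range(by.shape[1])],
            ))
        coords = df[["x", "y"]].to_numpy(float)
        n_xy = np.unique(coords, axis=0).shape[0]
        df_sp = min(spec.spline_df["spatial"], n_xy - 1)
        if df_sp >= 3:
            sp = thin_plate_basis(coords, df_sp)
        else:
            sp = coords - coords.mean(axis=0)  # too few locations for a smooth
        parts.append(pd.DataFrame(
            sp, index=df.index,
            columns=[f"spatial{i+1}" for i in range(sp.shape[1])],
        ))
    if spec.covariate_set == "model2":
        parts.append(_dummies(df["parity"].astype(int), (0, 1, 2), "parity"))
        parts.append(df[["bmi"]].astype(float))
        parts.append(df[["tobacco", "alcohol"]].astype(float))
        gam_levels = sorted(df["ga_method"].unique())
        parts.append(_dummies(df["ga_method"], gam_levels, "ga_method"))
        parts.append(_dummies(df["education"], EDUCATION_LEVELS, "education"))
    if spec.adjust_temperature:
        parts.append(df[["avg_temperature"]].astype(float))
    if spec.adjust_ambient_pm:
        parts.append(df[["avg_ambient_pm25"]].astype(float))
    for c in spec.extra_covariates:
        parts.append(df[[c]].astype(float))
    for c in extra_columns:
        parts.append(df[[c]].astype(float))
    X = pd.concat(parts, axis=1)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"design matrix has missing values in {bad}; impute first")
    return X


def _ensure_birth_year(df: pd.DataFrame) -> pd.DataFrame:
    if "birth_year" in df.columns or "conception_date" not in df.columns:
        return df
    df = df.copy()
    conc = pd.to_datetime(df["conception_date"])
    if "ga_days" in df.columns:
        df["birth_year"] = (conc + pd.to_timedelta(df["ga_days"], unit="D")).dt.year
    else:
        df["birth_year"] = conc.dt.year
    return df


def _drop_collinear(X: pd.DataFrame, keep: str | None = None, tol: float = 1e-9) -> pd.DataFrame:
    """Drop numerically collinear columns (rank-revealing pivoted QR), never
    dropping ``keep``."""
    from scipy.linalg import qr

    A = X.to_numpy(float)
    if keep is not None:
        # put the protected column first so QR pivots keep it
        cols = [keep] + [c for c in X.columns if c != keep]
        A = X[cols].to_numpy(float)
    else:
        cols = list(X.columns)
    _, R, piv = qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > tol * diag.max()).sum())
    kept = sorted(piv[:rank], key=lambda i: list(X.columns).index(cols[i]))
    if keep is not None and cols.index(keep) not in kept:
        kept = [cols.index(keep)] + kept[:-1]
    return X[[cols[i] for i in kept]]


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _fit_logistic(
    X: pd.DataFrame,
    y: np.ndarray,
    df: pd.DataFrame,
    spec: ModelSpec,
    exposure_term: str,
) -> tuple[pd.Series, pd.Series, float, bool, dict, pd.DataFrame, str]:
    """Dispatch on cluster mode; returns params, se, loglik, converged,
    variance components, covariance, method label."""
    if int(y.sum()) == 0:
        raise FitError("no events in the analysis table")
    names = list(X.columns)
    if spec.cluster_mode == "fixed_effects":
        sites = sorted(df[spec.cluster].unique())
        X = pd.concat([X, _dummies(df[spec.cluster], sites, "site")], axis=1)
        X = _drop_collinear(X, keep=exposure_term)
        names = list(X.columns)
    if spec.cluster_mode in ("none", "fixed_effects"):
        model = sm.Logit(y, X.to_numpy())
        try:
            res = model.fit(disp=0, method="newton", tol=1e-10, maxiter=200)
            converged = bool(res.mle_retvals["converged"])
            if not converged:
                res = model.fit(
                    disp=0, method="bfgs", maxiter=1000, gtol=1e-7,
                    start_params=res.params,
                )
                converged = bool(res.mle_retvals["converged"])
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            nan = pd.Series(np.nan, index=names)
            return nan, nan, float("nan"), False, {}, None, spec.cluster_mode
        params = pd.Series(res.params, index=names)
        try:
            se = pd.Series(res.bse, index=names)
            cov = pd.DataFrame(res.cov_params(), index=names, columns=names)
        except ValueError:  # singular Hessian (e.g. collinear site/spatial terms)
            se = pd.Series(np.nan, index=names)
            cov = None
            converged = False
        return params, se, float(res.llf), converged, {}, cov, spec.cluster_mode
    groups = df[spec.cluster].to_numpy()
    if spec.cluster_mode == "random_intercept":
        n_nodes = 1 if spec.method == "laplace" else spec.n_nodes
        r = fit_logistic_mixed(X.to_numpy(), y, groups, n_nodes=n_nodes)
    else:  # random_slope
        r = fit_logistic_mixed_slope(X.to_numpy(), y, df[exposure_term].to_numpy(float), groups)
    params = pd.Series(r.beta, index=names)
    se = pd.Series(r.se, index=names)
    cov = pd.DataFrame(r.cov[: len(names), : len(names)], index=names, columns=names)
    vc = {"site_intercept_sd": r.sigma, "site_intercept_sd_se": r.sigma_se}
    if r.sigma2 is not None:
        vc["site_slope_sd"] = r.sigma2
    return params, se, r.loglik, r.converged, vc, cov, r.method


def _bin_weeks(df: pd.DataFrame, min_events: int = 1) -> pd.Series:
    """Group gestational weeks so every indicator bin holds >= ``min_events``
    events (standard interval grouping for sparse discrete-time data; an
    event-free week's indicator is otherwise unidentified).  Each bin is
    labelled by its first week; with enough events per week this is the
    identity mapping."""
    weeks = sorted(df["gestational_week"].unique())
    events = df.groupby("gestational_week")["event"].sum()
    mapping: dict[int, int] = {}
    cur: list[int] = []
    acc = 0
    for w in weeks:
        cur.append(w)
        acc += int(events.get(w, 0))
        if acc >= min_events:
            for x in cur:
                mapping[x] = cur[0]
            cur, acc = [], 0
    if cur:  # trailing event-poor weeks merge backwards into the last bin
        last = mapping[max(mapping)] if mapping else cur[0]
        for x in cur:
            mapping[x] = last
    return df["gestational_week"].map(mapping)


def fit_pooled_logistic(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Pooled logistic regression on the person-period table.

    Returns the conditional OR per unit of the cumulative exposure term as
    ``exp(params[spec.exposure_term])``.
    """
    df = _ensure_birth_year(table)
    df = df.assign(gestational_week=_bin_weeks(df))
    X = build_design(df, spec, week_indicators=True)
    y = df["event"].to_numpy(float)
    params, se, ll, conv, vc, cov, method = _fit_logistic(X, y, df, spec, spec.exposure_term)
    return FitResult(
        params=params, se=se, exposure_term=spec.exposure_term, loglik=ll,
        converged=conv, n_rows=len(df), n_pregnancies=df["pregnancy_id"].nunique(),
        n_events=int(y.sum()), variance_components=vc, cov=cov,
        outcome="preterm_week", method=method,
    )


def fit_week_window_models(
    births: pd.DataFrame,
    weekly: pd.DataFrame,
    spec: ModelSpec,
    weeks: Sequence[int] = range(36),
    exposure_col: str = "days_gt0",
) -> dict[int, FitResult]:
    """Separate logistic models of preterm birth on smoke days within each
    gestational week 0..35.

    Each week-w model includes only births whose week w was fully observed
    before delivery (gestational age > 7*(w+1) days).  Weeks with zero
    exposure variance are returned flagged (converged=False) and not fitted.
    """
    weeks = list(weeks)
    if any(w < 0 or w > 35 for w in weeks):
        raise ValueError("weeks must lie in 0..35")
    wk = weekly[["pregnancy_id", "week", exposure_col]]
    out: dict[int, FitResult] = {}
    births = _ensure_birth_year(births)
    for w in weeks:
        term = f"week{w}_{exposure_col}"
        wk_w = wk.loc[wk["week"] == w, ["pregnancy_id", exposure_col]].rename(
            columns={exposure_col: term}
        )
        sub = births[births["ga_days"] > 7 * (w + 1)]
        sub = sub.merge(wk_w, on="pregnancy_id", how="inner")
        if sub[term].std() == 0 or sub["preterm"].sum() == 0:
            nan = pd.Series(np.nan, index=[term])
            out[w] = FitResult(
                params=nan, se=nan, exposure_term=term, loglik=float("nan"),
                converged=False, n_rows=len(sub), n_pregnancies=len(sub),
                n_events=int(sub["preterm"].sum()), outcome="preterm", method="skipped",
            )
            continue
        X = build_design(sub, spec, exposure_term=term)
        y = sub["preterm"].to_numpy(float)
        params, se, ll, conv, vc, cov, method = _fit_logistic(X, y, sub, spec, term)
        out[w] = FitResult(
            params=params, se=se, exposure_term=term, loglik=ll, converged=conv,
            n_rows=len(sub), n_pregnancies=len(sub), n_events=int(y.sum()),
            variance_components=vc, cov=cov, outcome="preterm", method=method,
        )
    return out


def fit_gestational_age_linear(
    births: pd.DataFrame,
    spec: ModelSpec,
    exposure_col: str,
    min_ga_days: int = 224,
) -> FitResult:
    """Linear model of gestational age at delivery (days) on exposure
    accumulated from conception to 32 weeks, with model-1 adjustment and a
    site random intercept.

    Births delivered before 32 weeks (GA < 224 days) are excluded so the
    exposure window is fixed across the analysis set.
    """
    sub = births[births["ga_days"] >= min_ga_days].copy()
    sub = _ensure_birth_year(sub)
    X = build_design(sub, spec, exposure_term=exposure_col)
    y = sub["ga_days"].to_numpy(float)
    names = list(X.columns)
    if spec.cluster_mode == "none":
        res = sm.OLS(y, X.to_numpy()).fit()
        params = pd.Series(res.params, index=names)
        se = pd.Series(res.bse, index=names)
        ll, conv, vc = float(res.llf), True, {}
        cov = pd.DataFrame(res.cov_params(), index=names, columns=names)
    else:
        md = sm.MixedLM(y, X.to_numpy(), groups=sub[spec.cluster].to_numpy())
        res = md.fit(reml=True)
        if not res.converged:
            # gradient optimizers stall when the site variance sits at 0
            res = md.fit(reml=True, method="powell")
        params = pd.Series(res.fe_params, index=names)
        se = pd.Series(res.bse_fe, index=names)
        ll, conv = float(res.llf), bool(res.converged)
        vc = {"site_intercept_sd": float(np.sqrt(np.asarray(res.cov_re)[0, 0])),
              "residual_sd": float(np.sqrt(res.scale))}
        cov = pd.DataFrame(
            np.asarray(res.cov_params())[: len(names), : len(names)],
            index=names, columns=names,
        )
    return FitResult(
        params=params, se=se, exposure_term=exposure_col, loglik=ll,
        converged=conv, n_rows=len(sub), n_pregnancies=len(sub),
        n_events=int((sub["ga_days"] < 259).sum()), variance_components=vc,
        cov=cov, outcome="gestational_age_days", family="linear", method="mixedlm",
    )


# ---------------------------------------------------------------------------
# effect modification
# ---------------------------------------------------------------------------

def poverty_tertiles(values: pd.Series) -> pd.Series:
    """Empirical tertiles of the neighbourhood poverty rate within the
    analysis sample."""
    return pd.Series(
        pd.qcut(values, 3, labels=["T1", "T2", "T3"]).astype(str), index=values.index
    )


@dataclass
class EffectModificationResult:
    modifier: str
    stratified: dict
    pooled: FitResult
    interaction_p: float
    interaction_df: int


def effect_modification(
    table: pd.DataFrame, spec: ModelSpec, modifier: str,
    min_stratum_births: int = 0,
) -> EffectModificationResult:
    """Stratified fits plus a pooled fit with exposure × modifier interaction.

    Binary modifiers give the Wald p of the single product term; categorical
    modifiers a multi-df Wald chi-square over all interaction coefficients.
    Strata with fewer than ``min_stratum_births`` pregnancies are omitted
    from the stratified fits (they stay in the pooled fit).
    """
    df = _ensure_birth_year(table)
    if modifier == "poverty_tertile" and modifier not in df.columns:
        per_preg = df.groupby("pregnancy_id")["poverty_rate"].first()
        df = df.merge(
            poverty_tertiles(per_preg).rename("poverty_tertile"),
            left_on="pregnancy_id", right_index=True,
        )
    levels = sorted(df[modifier].dropna().unique())
    if len(levels) < 2:
        raise ValueError(f"modifier {modifier!r} has fewer than 2 levels")
    df = df.assign(gestational_week=_bin_weeks(df))

    stratified = {}
    for lev in levels:
        sub = df[df[modifier] == lev]
        if sub["pregnancy_id"].nunique() < min_stratum_births:
            continue
        sub_spec = spec
        if modifier == "census_region" or modifier == "region":
            # spatial smooth is unstable within a single region at small n
            sub_spec = replace(spec, spline_df={**spec.spline_df, "spatial": 3})
        stratified[lev] = fit_pooled_logistic(sub, sub_spec)

    # pooled fit with interaction columns (reference level omitted)
    inter_cols = []
    df = df.copy()
    for lev in levels[1:]:
        col = f"{spec.exposure_term}:{modifier}[{lev}]"
        df[col] = df[spec.exposure_term].astype(float) * (df[modifier] == lev)
        inter_cols.append(col)
    X = build_design(df, spec, week_indicators=True, extra_columns=inter_cols)
    # the modifier's main effect must accompany the product terms; sex and
    # race are already in the model-1/2 design, other modifiers are added
    main_present = spec.covariate_set in ("model1", "model2") and modifier in ("infant_sex", "race")
    if not main_present:
        for lev in levels[1:]:
            X[f"{modifier}[{lev}]"] = (df[modifier] == lev).astype(float).to_numpy()
    y = df["event"].to_numpy(float)
    params, se, ll, conv, vc, cov, method = _fit_logistic(X, y, df, spec, spec.exposure_term)
    pooled = FitResult(
        params=params, se=se, exposure_term=spec.exposure_term, loglik=ll,
        converged=conv, n_rows=len(df), n_pregnancies=df["pregnancy_id"].nunique(),
        n_events=int(y.sum()), variance_components=vc, cov=cov,
        outcome="preterm_week", method=method,
    )
    # Wald test on the interaction block
    k = len(inter_cols)
    if cov is None or not conv:
        p = float("nan")
    else:
        b = params[inter_cols].to_numpy()
        V = cov.loc[inter_cols, inter_cols].to_numpy()
        chi2 = float(b @ np.linalg.solve(V, b))
        p = float(stats.chi2.sf(chi2, k))
    return EffectModificationResult(
        modifier=modifier, stratified=stratified, pooled=pooled,
        interaction_p=p, interaction_df=k,
    )


# ---------------------------------------------------------------------------
# sensitivity suite
# ---------------------------------------------------------------------------

def sensitivity_suite(
    table: pd.DataFrame,
    births: pd.DataFrame,
    spec: ModelSpec,
    trimester_columns: Sequence[str] = ("t1_mean", "t2_mean", "t3_mean"),
) -> dict[str, FitResult]:
    """The five sensitivity variants of the primary pooled analysis.

    1. trimester-specific exposure (birth-level logistic, three trimester
       coefficients fitted jointly);
    2. adjustment for pregnancy-average ambient temperature and ambient
       (non-wildfire) PM2.5 — requires those columns in the table;
    3. site fixed effects instead of random intercepts;
    4. site random intercept plus a site random slope on the exposure;
    5. complete case analysis (rows with any missing model covariate dropped).
    """
    out: dict[str, FitResult] = {}
    births = _ensure_birth_year(births)

    missing_tri = [c for c in trimester_columns if c not in births.columns]
    if missing_tri:
        raise ValueError(f"trimester exposure columns absent: {missing_tri}")
    X = build_design(births, spec, exposure_term=None)
    for c in trimester_columns:
        X[c] = births[c].astype(float).to_numpy()
    y = births["preterm"].to_numpy(float)
    params, se, ll, conv, vc, cov, method = _fit_logistic(
        X, y, births, spec, trimester_columns[0]
    )
    out["trimester_exposure"] = FitResult(
        params=params, se=se, exposure_term=trimester_columns[1], loglik=ll,
        converged=conv, n_rows=len(births), n_pregnancies=len(births),
        n_events=int(y.sum()), variance_components=vc, cov=cov,
        outcome="preterm", method=method,
    )

    if not (spec.adjust_temperature or spec.adjust_ambient_pm):
        if not {"avg_temperature", "avg_ambient_pm25"}.issubset(table.columns):
            raise ValueError(
                "confounder adjustment variant needs avg_temperature and "
                "avg_ambient_pm25 columns (simulate with include_confounders)"
            )
    out["confounder_adjusted"] = fit_pooled_logistic(
        table, replace(spec, adjust_temperature=True, adjust_ambient_pm=True)
    )
    out["site_fixed_effects"] = fit_pooled_logistic(
        table, replace(spec, cluster_mode="fixed_effects")
    )
    out["random_slope"] = fit_pooled_logistic(
        table, replace(spec, cluster_mode="random_slope")
    )
    complete = table.dropna(subset=_covariate_columns(table, spec))
    out["complete_case"] = fit_pooled_logistic(complete, spec)
    return out


def _covariate_columns(df: pd.DataFrame, spec: ModelSpec) -> list[str]:
    base = [spec.exposure_term]
    if spec.covariate_set in ("model1", "model2"):
        base += ["infant_sex", "age", "race", "hispanic", "poverty_rate",
                 "season_conception", "x", "y"]
    if spec.covariate_set == "model2":
        base += ["parity", "bmi", "tobacco", "alcohol", "ga_method", "education"]
    return [c for c in base if c in df.columns]
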