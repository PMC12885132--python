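"""Site-specific multiple imputation by chained equations, with Rubin pooling.

Chained-equation sweeps run independently within each study site (sites with
fewer than ``small_site_min`` records fall back to a pooled model with a site
indicator).  Imputation models by variable type:

* continuous — Bayesian linear regression with predictive mean matching
  (k nearest donors on the posterior-draw linear predictor);
* binary — logistic regression with an approximate posterior coefficient
  draw, imputing by Bernoulli sampling;
* categorical — ridge-regularised multinomial logistic regression fitted on
  a bootstrap resample (parameter uncertainty via the bootstrap), imputing by
  softmax sampling.

Predictors default to all other analysis covariates plus an exposure summary
and the outcome, the standard congenial choice for downstream outcome models.
Observed cells are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .models import FitResult


class ImputationError(ValueError):
    pass


@dataclass(frozen=True)
class ImputationSpec:
    """How many imputations, how many sweeps, and which model per variable."""

    m: int = 10
    max_iter: int = 10
    methods: Mapping[str, str] = field(default_factory=dict)  # var -> pmm|logistic|multinomial
    predictors: Sequence[str] | None = None   # default: all other covariates + exposure + outcome
    by_site: bool = True
    small_site_min: int = 50
    pmm_k: int = 5

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ImputationError("m must be >= 1 (>= 2 for pooling)")
        if self.max_iter < 1:
            raise ImputationError("max_iter must be >= 1")


def _infer_method(col: pd.Series) -> str:
    if col.dtype.kind in "fiu":
        vals = col.dropna().unique()
        if len(vals) <= 2:
            return "logistic"
        return "pmm"
    return "multinomial"


#: Default imputation-model predictors: the analysis covariates plus an
#: exposure summary (total smoke days) and the outcome.
DEFAULT_PREDICTORS = (
    "age", "infant_sex", "race", "hispanic", "education", "parity", "bmi",
    "tobacco", "alcohol", "poverty_rate", "ga_method", "season_conception",
    "days_gt0", "preterm",
)


def _design(df: pd.DataFrame, predictors: list[str], target: str) -> np.ndarray:
    cols = [c for c in predictors if c != target]
    parts = [np.ones((len(df), 1))]
    for c in cols:
        s = df[c]
        if s.dtype.kind in "fiu":
            v = s.to_numpy(float)
            v = np.where(np.isnan(v), np.nanmean(v), v)  # neutral fill for not-yet-imputed cells
            sd = v.std()
            parts.append(((v - v.mean()) / (sd if sd > 0 else 1.0))[:, None])
        else:
            filled = s.astype("object").where(s.notna(), "__missing__")
            levels = sorted(pd.unique(filled))
            for lev in levels[1:]:
                parts.append((filled == lev).to_numpy(float)[:, None])
    return np.concatenate(parts, axis=1)


def _psd_draw(rng: np.random.Generator, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Multivariate normal draw tolerating a semi-definite covariance."""
    w, V = np.linalg.eigh(0.5 * (cov + cov.T))
    w = np.clip(w, 0.0, None)
    return mean + (V * np.sqrt(w)) @ rng.standard_normal(len(mean))


def _impute_pmm(X, yobs_mask, y, rng, k):
    Xo, yo = X[yobs_mask], y[yobs_mask]
    n, p = Xo.shape
    ridge = 1e-6 * np.eye(p)
    XtX = Xo.T @ Xo + ridge
    beta_hat = np.linalg.solve(XtX, Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    dof = max(n - p, 2)
    sigma2 = float(resid @ resid) / dof
    sigma2_draw = sigma2 * dof / max(rng.chisquare(dof), 1e-8)
    cov = sigma2_draw * np.linalg.inv(XtX)
    beta_draw = _psd_draw(rng, beta_hat, cov)
    pred_obs = Xo @ beta_draw
    pred_mis = X[~yobs_mask] @ beta_draw
    out = np.empty(pred_mis.shape[0])
    kk = min(k, len(yo))
    for i, pm in enumerate(pred_mis):
        idx = np.argpartition(np.abs(pred_obs - pm), kk - 1)[:kk]
        out[i] = yo[idx[rng.integers(kk)]]
    return out


def _impute_logistic(X, yobs_mask, y, rng):
    Xo, yo = X[yobs_mask], y[yobs_mask]
    if len(np.unique(yo)) < 2:
        return np.full((~yobs_mask).sum(), yo[0])
    lr = LogisticRegression(C=10.0, max_iter=500)
    lr.fit(Xo[:, 1:], yo)  # sklearn adds its own intercept
    beta = np.concatenate([lr.intercept_, lr.coef_.ravel()])
    # approximate posterior draw from the observed information
    p = expit(Xo @ beta)
    w = np.clip(p * (1 - p), 1e-8, None)
    info = (Xo.T * w) @ Xo + 1e-4 * np.eye(Xo.shape[1])
    cov = np.linalg.inv(info)
    beta_draw = _psd_draw(rng, beta, cov)
    pm = expit(X[~yobs_mask] @ beta_draw)
    return (rng.random(len(pm)) < pm).astype(yo.dtype)


def _impute_multinomial(X, yobs_mask, y, rng):
    Xo, yo = X[yobs_mask], y[yobs_mask]
    levels = np.unique(yo)
    if len(levels) < 2:
        return np.full((~yobs_mask).sum(), yo[0])
    boot = rng.integers(len(yo), size=len(yo))  # bootstrap for parameter uncertainty
    Xb, yb = Xo[boot], yo[boot]
    if len(np.unique(yb)) < 2:
        Xb, yb = Xo, yo
    lr = LogisticRegression(C=10.0, max_iter=500)
    lr.fit(Xb[:, 1:], yb)
    probs = lr.predict_proba(X[~yobs_mask][:, 1:])
    cum = probs.cumsum(axis=1)
    u = rng.random(len(probs))[:, None]
    choice = (u > cum).sum(axis=1)
    return lr.classes_[choice]


def _chained_sweeps(
    df: pd.DataFrame, incomplete: list[str], predictors: list[str],
    spec: ImputationSpec, rng: np.random.Generator,
) -> pd.DataFrame:
    work = df.copy()
    masks = {v: df[v].isna().to_numpy() for v in incomplete}
    # initial fill: random draws from the observed marginal
    for v in incomplete:
        obs = df[v].dropna().to_numpy()
        work.loc[masks[v], v] = rng.choice(obs, size=int(masks[v].sum()))
    for _ in range(spec.max_iter):
        for v in incomplete:
            method = spec.methods.get(v) or _infer_method(df[v])
            mask = masks[v]
            work_v = work.copy()
            work_v.loc[mask, v] = np.nan
            X = _design(work_v, predictors, v)
            if method == "pmm":
                y = df[v].to_numpy(float)
                work.loc[mask, v] = _impute_pmm(X, ~mask, y, rng, spec.pmm_k)
            elif method == "logistic":
                y = df[v].to_numpy()
                work.loc[mask, v] = _impute_logistic(X, ~mask, y, rng)
            elif method == "multinomial":
                y = df[v].to_numpy()
                work.loc[mask, v] = _impute_multinomial(X, ~mask, y, rng)
            else:
                raise ImputationError(f"unknown imputation method {method!r}")
    return work


def mice_by_site(
    records: pd.DataFrame,
    spec: ImputationSpec,
    seed: int,
    variables: Sequence[str] | None = None,
) -> list[pd.DataFrame]:
    """Produce ``spec.m`` completed datasets via per-site chained equations.

    ``variables`` defaults to every column with missing values.  Within each
    site every incomplete variable must have at least one observed value,
    otherwise an error naming the site and variable is raised.
    """
    if variables is None:
        variables = [c for c in records.columns if records[c].isna().any()]
    variables = list(variables)
    if not variables:
        return [records.copy() for _ in range(spec.m)]

    if spec.predictors is not None:
        predictors = list(spec.predictors)
    else:
        predictors = [c for c in DEFAULT_PREDICTORS if c in records.columns]

    if spec.by_site:
        small = [
            s for s, g in records.groupby("site_id")
            if len(g) < spec.small_site_min
        ]
        for s, g in records.groupby("site_id"):
            if s in small:
                continue
            for v in variables:
                if g[v].notna().sum() == 0:
                    raise ImputationError(
                        f"variable {v!r} is entirely missing within site {s!r}"
                    )

    rng_master = np.random.default_rng(seed)
    out = []
    for _ in range(spec.m):
        rng = np.random.default_rng(rng_master.integers(2**31))
        if not spec.by_site:
            out.append(_chained_sweeps(records, variables, predictors, spec, rng))
            continue
        parts = []
        pooled_idx = records.index[records["site_id"].isin(small)]
        for s, g in records.groupby("site_id"):
            if s in small:
                continue
            sub_vars = [v for v in variables if g[v].isna().any()]
            parts.append(
                _chained_sweeps(g, sub_vars, predictors, spec, rng) if sub_vars else g.copy()
            )
        if len(pooled_idx):
            # small sites: pooled model with a site indicator as predictor
            g = records.loc[pooled_idx]
            sub_vars = [v for v in variables if g[v].isna().any()]
            preds = predictors + ["site_id"]
            parts.append(
                _chained_sweeps(g, sub_vars, preds, spec, rng) if sub_vars else g.copy()
            )
        done = pd.concat(parts).loc[records.index]
        out.append(done)
    return out


def rubin_pool(fits: Sequence[FitResult]) -> FitResult:
    """Combine fits on ``m`` imputed datasets by Rubin's rules.

    Pooled estimate = mean of estimates; total variance = mean within-fit
    variance + (1 + 1/m) x between-imputation variance; interval half-widths
    use the t distribution with the standard small-sample degrees of freedom.
    """
    if not fits:
        raise ImputationError("no fits to pool")
    m = len(fits)
    names = list(fits[0].params.index)
    for f in fits[1:]:
        if list(f.params.index) != names:
            raise ImputationError("fits have mismatched coefficient names")
    est = np.vstack([f.params.to_numpy(float) for f in fits])
    var = np.vstack([f.se.to_numpy(float) ** 2 for f in fits])
    qbar = est.mean(axis=0)
    ubar = var.mean(axis=0)
    t_df = None
    if m == 1:
        total = ubar
    else:
        b = est.var(axis=0, ddof=1)
        total = ubar + (1 + 1 / m) * b
        with np.errstate(divide="ignore"):
            lam = (1 + 1 / m) * b / total
            t_df = np.where(lam > 0, (m - 1) / lam**2, np.inf)
    se = np.sqrt(total)
    f0 = fits[0]
    return FitResult(
        params=pd.Series(qbar, index=names),
        se=pd.Series(se, index=names),
        exposure_term=f0.exposure_term,
        loglik=float(np.mean([f.loglik for f in fits])),
        converged=all(f.converged for f in fits),
        n_rows=f0.n_rows, n_pregnancies=f0.n_pregnancies,
        n_events=int(np.round(np.mean([f.n_events for f in fits]))),
        variance_components={"m": m},
        outcome=f0.outcome, family=f0.family, method=f"rubin_pool[{f0.method}]",
        t_df=None if t_df is None else pd.Series(t_df, index=names),
    )
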