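"""End-to-end pipeline: simulate → exposure metrics → cohort build →
(optional) imputation → models → tidy report.

Every stage is a plain function over in-memory tables; :func:`run_pipeline`
chains them under one configuration and seed, writes each artefact into the
output directory and echoes the configuration verbatim into the bundle, so a
run is reproducible bit for bit from its config file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import simulate as sim
from .exposure import THRESHOLDS, WAVE_DURATIONS, WAVE_THRESHOLDS, threshold_column
from .impute import ImputationSpec, mice_by_site, rubin_pool
from .models import (
    FitResult,
    ModelSpec,
    effect_modification,
    fit_gestational_age_linear,
)

log = logging.getLogger("smokeptb")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """One run's full configuration (seed is mandatory)."""

    seed: int
    output_dir: str = "smokeptb_output"
    # generator
    n_pregnancies: int = 5000
    n_sites: int = 30
    n_tracts_per_site: int = 10
    conception_start: date = date(2006, 1, 1)
    conception_end: date = date(2020, 3, 20)
    exposure_end_date: date = date(2020, 12, 31)
    move_fraction: float = 0.10
    missingness: str = "none"            # none | table1
    include_confounders: bool = False
    # models
    exposure_terms: tuple[str, ...] = (
        "cum_mean", "cum_days_gt0", "cum_days_ge2p5", "cum_days_ge5", "cum_days_ge10",
    )
    covariate_set: str = "model1"
    cluster_mode: str = "random_intercept"
    run_weekly_models: bool = False
    run_ga_model: bool = True
    run_effect_modification: tuple[str, ...] = ()
    run_sensitivity: bool = False
    # cohort build
    site_min_births: int = 100
    site_max_missing: float = 0.25
    # imputation
    imputation_m: int = 5
    imputation_max_iter: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "seed" not in raw:
            raise PipelineError("config: seed is mandatory")
        for k in ("conception_start", "conception_end", "exposure_end_date"):
            if k in raw and isinstance(raw[k], str):
                raw[k] = date.fromisoformat(raw[k])
        for k in ("exposure_terms", "run_effect_modification"):
            if k in raw:
                raw[k] = tuple(raw[k])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("conception_start", "conception_end", "exposure_end_date"):
            d[k] = d[k].isoformat()
        d["exposure_terms"] = list(d["exposure_terms"])
        d["run_effect_modification"] = list(d["run_effect_modification"])
        return d


def _fit_to_dict(fit: FitResult) -> dict:
    return {
        "exposure_term": fit.exposure_term,
        "coef": fit.exposure_coef if fit.exposure_term in fit.params.index else None,
        "params": {k: float(v) for k, v in fit.params.items()},
        "se": {k: float(v) for k, v in fit.se.items()},
        "loglik": fit.loglik,
        "converged": fit.converged,
        "n_rows": fit.n_rows,
        "n_pregnancies": fit.n_pregnancies,
        "n_events": fit.n_events,
        "variance_components": {k: float(v) for k, v in fit.variance_components.items()},
        "outcome": fit.outcome,
        "family": fit.family,
        "method": fit.method,
    }


def run_pipeline(config: PipelineConfig, write: bool = True) -> dict:
    """Execute the configured stages; returns the results bundle.

    Bundle keys: ``cohort`` (SyntheticCohort), ``person_period``, ``ledgers``,
    ``fits`` (analysis → FitResult or mapping), ``tables`` (tidy OR table and
    descriptive tables), ``config``.
    """
    from .models import fit_week_window_models, sensitivity_suite  # local: avoid cycle

    out_dir = Path(config.output_dir)
    bundle: dict = {"config": config.to_dict()}
    stage = "simulate"
    try:
        cc = sim.CohortConfig(
            n_pregnancies=config.n_pregnancies,
            n_sites=config.n_sites,
            n_tracts_per_site=config.n_tracts_per_site,
            conception_start=config.conception_start,
            conception_end=config.conception_end,
            exposure_end_date=config.exposure_end_date,
            seed=config.seed,
            move_fraction=config.move_fraction,
            missingness_spec=sim.TABLE1_MISSINGNESS if config.missingness == "table1" else (),
            include_confounders=config.include_confounders or config.run_sensitivity,
        )
        cohort = sim.simulate_cohort(cc)
        bundle["cohort"] = cohort
        log.info("simulate: %d pregnancies, %d tracts", len(cohort.pregnancies), len(cohort.tracts))

        stage = "build"
        births = cohort.pregnancies.merge(cohort.metrics, on="pregnancy_id")
        births["birth_year"] = (
            pd.to_datetime(births["conception_date"])
            + pd.to_timedelta(births["ga_days"], unit="D")
        ).dt.year
        included, ledger = cohort_mod.apply_inclusion_rules(
            births, config.exposure_end_date,
            cohort_mod.InclusionRules(
                conception_start=config.conception_start,
                conception_end=config.conception_end,
            ),
        )
        model1_cov = ["infant_sex", "age", "race", "hispanic", "poverty_rate"]
        included, site_ledger = cohort_mod.apply_site_exclusions(
            included, model1_cov,
            min_births=config.site_min_births, max_missing=config.site_max_missing,
        )
        table = cohort_mod.person_period_expand(included, cohort.cumulative)
        bundle["births"] = included
        bundle["person_period"] = table
        bundle["ledgers"] = {"inclusion": ledger, "sites": site_ledger.to_dict("records")}
        log.info("build: %d births -> %d person-period rows", len(included), len(table))

        stage = "impute"
        spec = ModelSpec(
            covariate_set=config.covariate_set, cluster_mode=config.cluster_mode
        )
        has_missing = included[cohort_mod_covariates(spec, included)].isna().any().any()
        imputations = None
        if has_missing:
            ispec = ImputationSpec(m=config.imputation_m, max_iter=config.imputation_max_iter)
            imputations = mice_by_site(included, ispec, seed=config.seed + 1)
            log.info("impute: m=%d datasets", len(imputations))

        stage = "fit"
        fits: dict = {}
        for term in config.exposure_terms:
            mspec = replace(spec, exposure_term=term)
            if imputations is None:
                fits[f"pooled:{term}"] = _fit_pooled(table, mspec)
            else:
                per_imp = []
                for imp in imputations:
                    t_imp = cohort_mod.person_period_expand(imp, cohort.cumulative)
                    per_imp.append(_fit_pooled(t_imp, mspec))
                fits[f"pooled:{term}"] = rubin_pool(per_imp)
        analysis_births = included.dropna(
            subset=cohort_mod_covariates(spec, included)
        ) if has_missing else included
        if config.run_ga_model:
            ga_births = _attach_week32_exposure(analysis_births, cohort.cumulative, "cum_days_gt0")
            fits["ga_linear"] = fit_gestational_age_linear(
                ga_births, replace(spec, exposure_term="exp_to_32w"), "exp_to_32w"
            )
        if config.run_weekly_models:
            fits["weekly"] = fit_week_window_models(
                analysis_births, cohort.weekly, replace(spec, exposure_term="days_gt0")
            )
        for modifier in config.run_effect_modification:
            t_cc = table.dropna(subset=cohort_mod_covariates(spec, table)) if has_missing else table
            fits[f"effect_modification:{modifier}"] = effect_modification(
                t_cc, replace(spec, exposure_term=config.exposure_terms[0]), modifier
            )
        if config.run_sensitivity:
            tri = _trimester_columns(cohort, analysis_births)
            t_sens = table
            if "avg_temperature" not in table.columns and "avg_temperature" in analysis_births.columns:
                conf_cols = analysis_births[["pregnancy_id", "avg_temperature", "avg_ambient_pm25"]]
                t_sens = table.merge(conf_cols, on="pregnancy_id")
            if has_missing:
                t_sens = t_sens.dropna(subset=cohort_mod_covariates(spec, t_sens))
            fits["sensitivity"] = sensitivity_suite(
                t_sens, tri, replace(spec, exposure_term=config.exposure_terms[0])
            )
        bundle["fits"] = fits

        stage = "report"
        bundle["tables"] = tabulate_results(bundle)
        if write:
            _write_bundle(bundle, out_dir, config)
    except Exception as e:
        raise PipelineError(f"stage {stage!r} failed: {e}") from e
    return bundle


def _fit_pooled(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    from .models import fit_pooled_logistic

    return fit_pooled_logistic(table, spec)


def cohort_mod_covariates(spec: ModelSpec, df: pd.DataFrame) -> list[str]:
    from .models import _covariate_columns

    cols = _covariate_columns(df, spec)
    return [c for c in cols if not c.startswith("cum_")]


def _attach_week32_exposure(
    births: pd.DataFrame, cumulative: pd.DataFrame, metric: str
) -> pd.DataFrame:
    w32 = cumulative[cumulative["week"] == 32][["pregnancy_id", metric]]
    w32 = w32.rename(columns={metric: "exp_to_32w"})
    return births.merge(w32, on="pregnancy_id", how="inner")


def _trimester_columns(cohort: sim.SyntheticCohort, births: pd.DataFrame) -> pd.DataFrame:
    """Birth-level trimester mean-daily exposure columns (t1/t2/t3_mean)."""
    mat = cohort.exposure_matrix
    ids = cohort.pregnancies["pregnancy_id"].to_numpy()
    valid = ~np.isnan(mat)
    filled = np.where(valid, mat, 0.0)
    out = pd.DataFrame({"pregnancy_id": ids})
    for name, (a, b) in {"t1": (0, 91), "t2": (91, 189), "t3": (189, mat.shape[1])}.items():
        n = valid[:, a:b].sum(axis=1)
        with np.errstate(invalid="ignore"):
            out[f"{name}_mean"] = np.where(n > 0, filled[:, a:b].sum(axis=1) / np.maximum(n, 1), 0.0)
    return births.merge(out, on="pregnancy_id", how="left")


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def tabulate_results(bundle: Mapping) -> dict[str, pd.DataFrame]:
    """Tidy result tables: a long OR table plus descriptive cohort tables."""
    rows = []

    def add(analysis: str, fit: FitResult, stratum: str = ""):
        if fit.exposure_term not in fit.params.index or not np.isfinite(fit.params[fit.exposure_term]):
            rows.append({"analysis": analysis, "exposure": fit.exposure_term,
                         "stratum": stratum, "estimate": np.nan, "status": "absent"})
            return
        coef = fit.exposure_coef
        lo, hi = fit.ci_low[fit.exposure_term], fit.ci_high[fit.exposure_term]
        is_or = fit.family == "logistic"
        rows.append({
            "analysis": analysis, "exposure": fit.exposure_term, "stratum": stratum,
            "estimate": float(np.exp(coef)) if is_or else coef,
            "ci_low": float(np.exp(lo)) if is_or else float(lo),
            "ci_high": float(np.exp(hi)) if is_or else float(hi),
            "scale": "OR" if is_or else "days",
            "n": fit.n_pregnancies, "events": fit.n_events,
            "status": "ok" if fit.converged else "not_converged",
        })

    for name, fit in bundle.get("fits", {}).items():
        if isinstance(fit, FitResult):
            add(name, fit)
        elif isinstance(fit, dict):  # weekly or sensitivity maps
            for key, f in fit.items():
                add(f"{name}[{key}]", f)
        else:  # effect modification
            add(name, fit.pooled, stratum="pooled+interaction")
            rows[-1]["interaction_p"] = fit.interaction_p
            for lev, f in fit.stratified.items():
                add(name, f, stratum=str(lev))

    or_table = pd.DataFrame(rows)
    tables = {"or_table": or_table}
    if "cohort" in bundle:
        cohort = bundle["cohort"]
        births = bundle.get("births", cohort.pregnancies.merge(cohort.metrics, on="pregnancy_id"))
        tables["descriptive_population"] = describe_population(births)
        tables["descriptive_exposure"] = describe_exposure(births)
        tables["smoke_wave_prevalence"] = wave_prevalence_table(births)
    return tables


def describe_population(births: pd.DataFrame) -> pd.DataFrame:
    """Population characteristics by preterm status (Table-1 style)."""
    rows = []
    groups = {"overall": births}
    if "preterm" in births.columns:
        groups = {"preterm": births[births["preterm"] == 1],
                  "term": births[births["preterm"] == 0], **groups}
    for var in ("age", "bmi", "poverty_rate"):
        if var not in births.columns:
            continue
        row = {"variable": var, "statistic": "mean (sd)"}
        for gname, g in groups.items():
            row[gname] = f"{g[var].mean():.1f} ({g[var].std():.1f})"
        rows.append(row)
    for var in ("infant_sex", "race", "education", "parity", "season_conception", "region"):
        if var not in births.columns:
            continue
        for lev in sorted(births[var].dropna().unique(), key=str):
            row = {"variable": var, "statistic": str(lev)}
            for gname, g in groups.items():
                n = int((g[var] == lev).sum())
                row[gname] = f"{n} ({100 * n / max(len(g), 1):.1f}%)"
            rows.append(row)
    return pd.DataFrame(rows)


def describe_exposure(births: pd.DataFrame) -> pd.DataFrame:
    """Exposure metrics overall and by subgroup (Table-2 style)."""
    def summarise(g: pd.DataFrame) -> dict:
        out = {
            "n": len(g),
            "preterm_rate": g["preterm"].mean() if "preterm" in g else np.nan,
            "mean_daily_pm25": g["mean_daily"].mean(),
        }
        for t in THRESHOLDS:
            c = threshold_column(t)
            out[f"mean_{c}"] = g[c].mean()
        return out

    rows = [{"group": "overall", "level": "", **summarise(births)}]
    for var in ("region", "infant_sex", "race", "hispanic"):
        if var not in births.columns:
            continue
        for lev in sorted(births[var].dropna().unique(), key=str):
            rows.append({"group": var, "level": str(lev), **summarise(births[births[var] == lev])})
    return pd.DataFrame(rows)


def wave_prevalence_table(births: pd.DataFrame) -> pd.DataFrame:
    """Share of pregnancies with >= 1 smoke wave, by intensity and duration
    (Table-3 style); monotone non-increasing along each row by construction."""
    rows = []
    for t in WAVE_THRESHOLDS:
        key = ("%g" % t).replace(".", "p")
        row = {"threshold_ugm3": t}
        for d in WAVE_DURATIONS:
            col = f"waves_ge{key}_d{d}"
            row[f"ge{d}_days_pct"] = float(100 * (births[col] >= 1).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def _write_bundle(bundle: dict, out_dir: Path, config: PipelineConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    cohort = bundle["cohort"]
    cohort.pregnancies.to_csv(out_dir / "cohort.csv", index=False)
    cohort.residence.to_csv(out_dir / "residence.csv", index=False)
    if len(cohort.series) <= 60:  # keep the long tract-day table manageable
        from .exposure import series_store_to_frame

        series_store_to_frame(cohort.series).to_csv(out_dir / "tract_series.csv", index=False)
    cohort.metrics.to_csv(out_dir / "exposure_metrics.csv", index=False)
    bundle["person_period"].to_csv(out_dir / "person_period.csv", index=False)
    (out_dir / "exclusion_ledgers.json").write_text(json.dumps(bundle["ledgers"], indent=2))
    fits_json = {}
    for name, fit in bundle["fits"].items():
        if isinstance(fit, FitResult):
            fits_json[name] = _fit_to_dict(fit)
        elif isinstance(fit, dict):
            fits_json[name] = {str(k): _fit_to_dict(f) for k, f in fit.items()}
        else:
            fits_json[name] = {
                "pooled": _fit_to_dict(fit.pooled),
                "interaction_p": fit.interaction_p,
                "stratified": {str(k): _fit_to_dict(f) for k, f in fit.stratified.items()},
            }
    (out_dir / "fits.json").write_text(json.dumps(fits_json, indent=2))
    for name, df in bundle["tables"].items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
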