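"""Synthetic cohort generator with a known discrete-time preterm-birth hazard.

Every downstream stage (exposure metrics, person-period expansion, pooled
logistic regression, imputation) is exercisable against this generator's
ground truth.  It emulates:

* episodic, zero-inflated, autocorrelated daily wildfire PM2.5 at census-tract
  level — a two-state (smoke / no-smoke) Markov chain whose entry probability
  varies seasonally, by census region and by a tract-level gamma frailty, with
  lognormal smoke-day concentrations that share a run-level intensity so that
  multi-day smoke waves are coherent events rather than independent draws;
* pregnancies clustered in study sites across the four US census regions, with
  covariate marginals approximating a large US pregnancy cohort (mean age at
  delivery 30.6 y, ~8.4% preterm, ~22 smoke days per pregnancy, ...);
* outcomes from a weekly discrete-time hazard over gestational weeks 22–36:
  logit(h_iw) = baseline_w + beta_exposure * cumexp_i(w) + covariates + site
  intercept, with term gestational ages drawn from a categorical distribution
  over 37–42 completed weeks;
* configurable MCAR/MAR covariate missingness for the imputation stage.

Gestational time: day 0 = conception, week w = days [7w, 7w+6], preterm means
gestational age < 259 days (37 completed weeks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .exposure import (
    DailySeries,
    PRETERM_CUTOFF_DAYS,
    cohort_cumulative_table,
    cohort_metrics_table,
    cohort_weekly_table,
)

REGIONS = ("West", "Midwest", "South", "Northeast")
#: Share of births by census region (cohort marginals: 29.0 / 17.8 / 21.4 / 31.8%).
REGION_SHARES = {"West": 0.290, "Midwest": 0.178, "South": 0.214, "Northeast": 0.318}
#: Rough lon/lat boxes per region for synthetic site/tract coordinates.
REGION_BOXES = {
    "West": (-124.0, -104.0, 32.0, 48.0),
    "Midwest": (-103.0, -83.0, 37.0, 48.0),
    "South": (-105.0, -77.0, 26.0, 37.0),
    "Northeast": (-80.0, -67.0, 38.0, 47.0),
}

RISK_WEEKS = tuple(range(22, 37))  # at-risk gestational weeks for preterm birth


class ParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExposureProcessParams:
    """Two-state seasonal Markov chain with run-level lognormal intensities.

    The stationary smoke-day fraction at mean modulation is
    ``p_enter / (p_enter + 1 - p_stay)`` in closed form.

    Intensity on smoke days is ``exp(intensity_log_mean + run_effect +
    day_noise)`` where ``run_effect ~ N(0, intensity_log_sd^2)`` is shared by
    all days of one consecutive smoke run and ``day_noise ~ N(0,
    intensity_day_log_sd^2)`` is day-specific.  The run-level component makes
    high-intensity smoke waves (all days above a threshold) realistically
    common.  ``stay_intensity_slope`` couples run persistence to run
    intensity: the per-day log-odds of remaining in the smoke state are
    ``logit(p_stay_smoke) + slope * run_effect``, so major smoke episodes are
    both more intense and longer-lasting (with slope 0 the chain is the plain
    two-state Markov chain and the closed-form stationary fraction applies
    exactly).  ``tract_rate_shape`` is the shape of a mean-1 gamma frailty
    multiplying ``p_enter`` per tract: it produces the strong between-tract
    overdispersion of smoke-day counts and a small fraction of pregnancies
    with no smoke exposure at all.
    """

    p_enter_smoke: float = 0.050
    p_stay_smoke: float = 0.46
    intensity_log_mean: float = 0.95   # log µg/m³, regional scaler applies on top
    intensity_log_sd: float = 0.78     # run-level SD (log scale)
    intensity_day_log_sd: float = 0.41 # day-level SD within a run (log scale)
    stay_intensity_slope: float = 0.55 # log-odds of persisting per unit run effect
    stay_age_decay: float = 0.55       # one-step log-odds drop in persistence once a run is 2+ days old
    stay_intensity_slope2: float = 0.12 # extra intensity slope for runs already 2+ days old
    seasonal_amplitude: float = 0.65   # relative modulation of p_enter
    seasonal_peak_doy: int = 227       # mid-August fire-season peak
    tract_rate_shape: float = 3.4      # gamma frailty shape (mean 1)
    region_scalers: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            # (rate multiplier on p_enter, multiplier on smoke-day intensity)
            "West": (1.00, 1.22),
            "Midwest": (1.74, 0.80),
            "South": (0.67, 1.02),
            "Northeast": (0.81, 0.88),
        }
    )

    def __post_init__(self) -> None:
        for name in ("p_enter_smoke", "p_stay_smoke"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name}={p} outside [0, 1]")
        if self.intensity_log_sd <= 0 or self.intensity_day_log_sd < 0:
            raise ParameterError("intensity log-SDs must be positive")
        if not 0.0 <= self.seasonal_amplitude < 1.0:
            raise ParameterError("seasonal_amplitude must be in [0, 1)")
        if self.tract_rate_shape <= 0:
            raise ParameterError("tract_rate_shape must be > 0")

    @property
    def stationary_smoke_fraction(self) -> float:
        """Closed-form stationary smoke-day fraction at mean modulation."""
        denom = self.p_enter_smoke + 1.0 - self.p_stay_smoke
        return 0.0 if denom == 0 else self.p_enter_smoke / denom


def default_baseline_logit() -> np.ndarray:
    """Per-week baseline log-odds of delivery, gestational weeks 22..36.

    Calibrated so the default cohort's marginal preterm fraction is ~8.4%
    split ~1.0% (<32 w), ~0.9% (32–33 w) and ~6.4% (34–36 w), after averaging
    over covariate effects, the exposure effect and site intercepts.
    """
    # reference-level weekly hazards; rising geometrically through week 31,
    # then stepping up to the late-preterm plateau
    hazards = np.array(
        [2.02e-4, 2.63e-4, 3.41e-4, 4.44e-4, 5.76e-4,
         7.50e-4, 9.74e-4, 1.264e-3, 1.646e-3, 2.136e-3,  # weeks 22..31
         3.871e-3, 4.067e-3,                              # weeks 32..33
         1.793e-2, 1.842e-2, 1.901e-2]                    # weeks 34..36
    )
    return logit(hazards)


@dataclass(frozen=True)
class HazardParams:
    """Data-generating discrete-time hazard for preterm delivery."""

    baseline_logit: np.ndarray = field(default_factory=default_baseline_logit)
    beta_exposure: float = math.log(1.02)
    exposure_metric: str = "cum_days_ge10"
    beta_covariates: Mapping[str, float] = field(
        default_factory=lambda: {
            "age_c": 0.05, "age_c2": 0.08, "female": -0.05,
            "race_black": 0.45, "race_aian": 0.60, "race_asian": 0.05,
            "race_multi": 0.05, "hispanic": 0.05,
            "poverty_c": 0.13, "bmi_c": 0.08, "tobacco": 0.25,
        }
    )
    sigma_site: float = 0.3
    term_ga_distribution: Mapping[int, float] = field(
        default_factory=lambda: {37: 0.08, 38: 0.22, 39: 0.38, 40: 0.22, 41: 0.08, 42: 0.02}
    )

    def __post_init__(self) -> None:
        b = np.asarray(self.baseline_logit, dtype=float)
        if b.shape != (15,):
            raise ParameterError("baseline_logit must have exactly 15 entries (weeks 22..36)")
        object.__setattr__(self, "baseline_logit", b)
        if self.sigma_site < 0:
            raise ParameterError("sigma_site must be >= 0")
        weeks = sorted(self.term_ga_distribution)
        if weeks != list(range(37, 37 + len(weeks))) or weeks[0] != 37:
            raise ParameterError("term_ga_distribution must cover weeks 37..42")
        if abs(sum(self.term_ga_distribution.values()) - 1.0) > 1e-9:
            raise ParameterError("term_ga_distribution must sum to 1")


@dataclass(frozen=True)
class MissingnessRule:
    """Masking rule for one covariate: MCAR at ``rate``, or MAR with the rate
    varying over the levels of a fully observed conditioning covariate."""

    variable: str
    mechanism: str = "MCAR"  # none | MCAR | MAR
    rate: float = 0.0
    depends_on: str | None = None
    rate_by_level: Mapping[object, float] | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in ("none", "MCAR", "MAR"):
            raise ParameterError(f"unknown missingness mechanism {self.mechanism!r}")
        if not 0.0 <= self.rate <= 1.0:
            raise ParameterError("missingness rate must be in [0, 1]")
        if self.mechanism == "MAR":
            if self.depends_on is None or self.rate_by_level is None:
                raise ParameterError("MAR rule needs depends_on and rate_by_level")
            for r in self.rate_by_level.values():
                if not 0.0 <= r <= 1.0:
                    raise ParameterError("MAR rates must be in [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort size, geography, conception window and seed."""

    n_pregnancies: int = 20_000
    n_sites: int = 30
    n_tracts_per_site: int = 40
    conception_start: date = date(2006, 1, 1)
    conception_end: date = date(2020, 3, 20)
    exposure_end_date: date = date(2020, 12, 31)
    seed: int = 0
    move_fraction: float = 0.10
    missingness_spec: tuple[MissingnessRule, ...] = ()
    include_confounders: bool = False

    def __post_init__(self) -> None:
        if self.n_pregnancies <= 0 or self.n_sites <= 0 or self.n_tracts_per_site <= 0:
            raise ParameterError("counts must be positive")
        if self.conception_end < self.conception_start:
            raise ParameterError("empty conception window")
        if not 0.0 <= self.move_fraction <= 1.0:
            raise ParameterError("move_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# exposure series simulation
# ---------------------------------------------------------------------------

def _seasonal_factor(doy: np.ndarray, amplitude: float, peak_doy: int) -> np.ndarray:
    return 1.0 + amplitude * np.cos(2.0 * np.pi * (doy - peak_doy) / 365.25)


def simulate_series_store(
    params: ExposureProcessParams,
    tracts: pd.DataFrame,
    start: date,
    end: date,
    seed: int,
) -> dict[str, DailySeries]:
    """Simulate daily series for every tract in ``tracts`` over [start, end].

    ``tracts`` needs columns ``tract_id, region, frailty``.  Non-smoke days
    are exactly 0.  Deterministic given (params, tracts, dates, seed).
    """
    if end < start:
        raise ParameterError("empty date range")
    n_days = (end - start).days + 1
    n_tracts = len(tracts)
    rng = np.random.default_rng(seed)

    region = tracts["region"].to_numpy()
    rate_scaler = np.array([params.region_scalers[r][0] for r in region])
    intensity_scaler = np.array([params.region_scalers[r][1] for r in region])
    frailty = tracts["frailty"].to_numpy(dtype=float)

    doy = np.array(
        [(start + timedelta(days=d)).timetuple().tm_yday for d in range(n_days)], dtype=float
    )
    season = _seasonal_factor(doy, params.seasonal_amplitude, params.seasonal_peak_doy)
    p_enter = np.clip(
        params.p_enter_smoke * rate_scaler[:, None] * frailty[:, None] * season[None, :],
        0.0, 0.95,
    )
    u = rng.random((n_tracts, n_days))
    run_draws = rng.normal(0.0, params.intensity_log_sd, size=(n_tracts, n_days))
    day_noise = rng.normal(0.0, params.intensity_day_log_sd, size=(n_tracts, n_days))

    state = np.zeros((n_tracts, n_days), dtype=bool)
    run_effect = np.zeros((n_tracts, n_days))
    prev = np.zeros(n_tracts, dtype=bool)
    cur_eff = np.zeros(n_tracts)
    if params.p_stay_smoke in (0.0, 1.0):
        base_stay_logit = logit(np.clip(params.p_stay_smoke, 1e-12, 1 - 1e-12))
    else:
        base_stay_logit = logit(params.p_stay_smoke)
    slope = params.stay_intensity_slope
    slope2 = params.stay_intensity_slope2
    decay = params.stay_age_decay
    age = np.zeros(n_tracts)
    plain = slope == 0.0 and decay == 0.0 and slope2 == 0.0
    for j in range(n_days):
        if plain:
            p_stay_j = params.p_stay_smoke
        else:
            p_stay_j = expit(
                base_stay_logit + slope * cur_eff
                + (slope2 * cur_eff - decay) * np.minimum(age - 1.0, 1.0)
            )
        thr = np.where(prev, p_stay_j, p_enter[:, j])
        now = u[:, j] < thr
        entering = now & ~prev
        cur_eff = np.where(entering, run_draws[:, j], cur_eff)
        age = np.where(now, np.where(entering, 1.0, age + 1.0), 0.0)
        run_effect[:, j] = cur_eff
        state[:, j] = now
        prev = now

    log_int = params.intensity_log_mean + run_effect + day_noise
    values = np.where(state, np.exp(log_int), 0.0)
    values *= intensity_scaler[:, None]

    out = {}
    ids = tracts["tract_id"].astype(str).to_numpy()
    for i, tid in enumerate(ids):
        out[tid] = DailySeries(tract_id=tid, start_date=start, values=values[i])
    return out


def simulate_tract_series(
    params: ExposureProcessParams,
    tract: Mapping[str, object],
    dates: tuple[date, date],
    seed: int,
) -> DailySeries:
    """Single-tract convenience wrapper around :func:`simulate_series_store`.

    ``tract`` needs keys ``tract_id``, ``region`` and optionally ``frailty``
    (default 1.0)."""
    row = {"tract_id": str(tract["tract_id"]),
           "region": tract.get("region", "West"),
           "frailty": float(tract.get("frailty", 1.0))}
    store = simulate_series_store(params, pd.DataFrame([row]), dates[0], dates[1], seed)
    return store[row["tract_id"]]


def simulate_confounder_series(
    tracts: pd.DataFrame, start: date, end: date, seed: int
) -> dict[str, pd.DataFrame]:
    """Daily ambient temperature (°C) and non-wildfire ambient PM2.5 (µg/m³)
    per tract, for the confounder-adjustment sensitivity variant.

    Temperature: latitude-dependent seasonal sinusoid + AR(1) noise.
    Ambient PM2.5: lognormal AR(1) around a regional mean.
    """
    n_days = (end - start).days + 1
    rng = np.random.default_rng(seed)
    doy = np.array(
        [(start + timedelta(days=d)).timetuple().tm_yday for d in range(n_days)], dtype=float
    )
    out = {}
    for row in tracts.itertuples(index=False):
        lat = getattr(row, "y", 40.0)
        base = 24.0 - 0.45 * (lat - 30.0)
        seasonal = base + 11.0 * np.cos(2 * np.pi * (doy - 200) / 365.25)
        ar = np.empty(n_days)
        ar[0] = rng.normal(0, 3)
        eps = rng.normal(0, 1.5, n_days)
        for j in range(1, n_days):
            ar[j] = 0.8 * ar[j - 1] + eps[j]
        temp = seasonal + ar
        logpm = np.empty(n_days)
        logpm[0] = rng.normal(2.0, 0.3)
        epsp = rng.normal(0, 0.25, n_days)
        for j in range(1, n_days):
            logpm[j] = 0.6 * logpm[j - 1] + 0.4 * 2.0 + epsp[j]
        out[str(row.tract_id)] = pd.DataFrame(
            {"temperature": temp, "ambient_pm25": np.exp(logpm)},
            index=pd.date_range(start, end),
        )
    return out


# ---------------------------------------------------------------------------
# sites, tracts, pregnancies
# ---------------------------------------------------------------------------

def _allocate_regions(n_sites: int) -> list[str]:
    """Largest-remainder allocation of sites to regions by birth share."""
    quotas = {r: REGION_SHARES[r] * n_sites for r in REGIONS}
    counts = {r: int(math.floor(q)) for r, q in quotas.items()}
    short = n_sites - sum(counts.values())
    for r in sorted(REGIONS, key=lambda r: quotas[r] - counts[r], reverse=True)[:short]:
        counts[r] += 1
    out = []
    for r in REGIONS:
        out.extend([r] * counts[r])
    return out


def make_sites(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    regions = _allocate_regions(config.n_sites)
    weights = rng.gamma(2.0, 1.0, size=config.n_sites)
    rows = []
    for i, region in enumerate(regions):
        x0, x1, y0, y1 = REGION_BOXES[region]
        rows.append(
            {
                "site_id": f"S{i:02d}",
                "region": region,
                "weight": weights[i],
                "x": rng.uniform(x0, x1),
                "y": rng.uniform(y0, y1),
            }
        )
    sites = pd.DataFrame(rows)
    # pregnancy-level site probabilities respecting regional birth shares
    share = sites["region"].map(REGION_SHARES)
    sites["p_site"] = share * sites["weight"] / sites.groupby("region")["weight"].transform("sum")
    sites["p_site"] /= sites["p_site"].sum()
    return sites


def make_tracts(
    sites: pd.DataFrame, config: CohortConfig, params: ExposureProcessParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    for site in sites.itertuples(index=False):
        for j in range(config.n_tracts_per_site):
            rows.append(
                {
                    "tract_id": f"{site.site_id}T{j:03d}",
                    "site_id": site.site_id,
                    "region": site.region,
                    "x": site.x + rng.normal(0, 0.3),
                    "y": site.y + rng.normal(0, 0.3),
                    "frailty": rng.gamma(params.tract_rate_shape, 1.0 / params.tract_rate_shape),
                    "poverty_rate": float(
                        np.clip(rng.gamma(1.32, 11.14), 0.0, 80.0)
                    ),
                }
            )
    return pd.DataFrame(rows)


#: Covariate marginal distributions the generator draws from (documented
#: defaults approximating a large US pregnancy cohort; categories renormalised
#: over observed values).
COVARIATE_MARGINALS = {
    "age_mean": 30.6, "age_sd": 5.6,
    "p_female": 0.488,
    "race_probs": {
        "White": 0.669, "Black": 0.137, "AsianNHPI": 0.072,
        "AIAN": 0.021, "MultiOther": 0.101,
    },
    "p_hispanic": 0.22,
    "education_probs": {
        "hs_or_less": 0.253, "some_college": 0.223,
        "bachelor": 0.274, "postgraduate": 0.250,
    },
    "parity_probs": {0: 0.406, 1: 0.353, 2: 0.241},  # 2 means ">=2"
    "bmi_mean": 26.8, "bmi_sd": 6.6,
    "p_tobacco": 0.081,
    "p_alcohol": 0.198,
    "ga_method_probs": {
        "obstetric_consensus": 0.45, "neonatal": 0.15,
        "lmp_ultrasound": 0.25, "edd_admin": 0.10, "self_report": 0.05,
    },
}


def simulate_pregnancies(
    config: CohortConfig,
    params: ExposureProcessParams,
    rng: np.random.Generator | None = None,
    sites: pd.DataFrame | None = None,
    tracts: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Outcome-free pregnancy records with covariates and residential history.

    Returns ``(pregnancies, residence, sites, tracts)``.  Each pregnancy has a
    conception date in the configured window, a site/tract, at least one
    residence interval covering the whole pregnancy (a ``move_fraction`` share
    has one mid-pregnancy move to another tract of the same site), and
    covariates drawn from :data:`COVARIATE_MARGINALS`.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if sites is None:
        sites = make_sites(config, rng)
    if tracts is None:
        tracts = make_tracts(sites, config, params, rng)
    n = config.n_pregnancies
    m = COVARIATE_MARGINALS

    site_idx = rng.choice(len(sites), size=n, p=sites["p_site"].to_numpy())
    site_id = sites["site_id"].to_numpy()[site_idx]
    tract_choices = {
        s: g["tract_id"].to_numpy() for s, g in tracts.groupby("site_id")
    }
    tract_id = np.array(
        [tract_choices[s][rng.integers(len(tract_choices[s]))] for s in site_id]
    )
    window_days = (config.conception_end - config.conception_start).days
    conception = np.array(
        [config.conception_start + timedelta(days=int(d))
         for d in rng.integers(0, window_days + 1, size=n)]
    )
    race_levels = list(m["race_probs"])
    edu_levels = list(m["education_probs"])
    parity_levels = list(m["parity_probs"])
    gam_levels = list(m["ga_method_probs"])
    tract_pov = tracts.set_index("tract_id")["poverty_rate"]
    tract_xy = tracts.set_index("tract_id")[["x", "y"]]

    preg = pd.DataFrame(
        {
            "pregnancy_id": [f"P{i:06d}" for i in range(n)],
            "site_id": site_id,
            "tract_id": tract_id,
            "region": sites["region"].to_numpy()[site_idx],
            "conception_date": conception,
            "age": np.clip(rng.normal(m["age_mean"], m["age_sd"], n), 14.0, 50.0),
            "infant_sex": np.where(rng.random(n) < m["p_female"], "female", "male"),
            "race": rng.choice(race_levels, size=n, p=list(m["race_probs"].values())),
            "hispanic": (rng.random(n) < m["p_hispanic"]).astype(int),
            "education": rng.choice(edu_levels, size=n, p=list(m["education_probs"].values())),
            "parity": rng.choice(parity_levels, size=n, p=list(m["parity_probs"].values())),
            "bmi": np.clip(rng.normal(m["bmi_mean"], m["bmi_sd"], n), 15.0, 60.0),
            "tobacco": (rng.random(n) < m["p_tobacco"]).astype(int),
            "alcohol": (rng.random(n) < m["p_alcohol"]).astype(int),
            "ga_method": rng.choice(gam_levels, size=n, p=list(m["ga_method_probs"].values())),
            "plurality": 1,
        }
    )
    preg["poverty_rate"] = tract_pov.loc[preg["tract_id"]].to_numpy()
    preg["x"] = tract_xy["x"].loc[preg["tract_id"]].to_numpy()
    preg["y"] = tract_xy["y"].loc[preg["tract_id"]].to_numpy()
    preg["season_conception"] = [_season(d) for d in preg["conception_date"]]

    # residential history: cover conception-30d .. conception+330d
    moves = rng.random(n) < config.move_fraction
    move_day = rng.integers(20, 280, size=n)
    rows = []
    for i in range(n):
        c = conception[i]
        start = c - timedelta(days=30)
        end = c + timedelta(days=330)
        if moves[i]:
            options = tract_choices[site_id[i]]
            new_tract = options[rng.integers(len(options))]
            mid = c + timedelta(days=int(move_day[i]))
            rows.append((preg["pregnancy_id"][i], tract_id[i], start, mid))
            rows.append((preg["pregnancy_id"][i], new_tract, mid, end))
        else:
            rows.append((preg["pregnancy_id"][i], tract_id[i], start, end))
    residence = pd.DataFrame(rows, columns=["pregnancy_id", "tract_id", "start_date", "end_date"])
    preg.attrs["seed"] = config.seed
    residence.attrs["seed"] = config.seed
    return preg, residence, sites, tracts


def _season(d: date) -> str:
    return {1: "winter", 2: "spring", 3: "summer", 4: "autumn"}[(d.month - 1) // 3 + 1]


def hazard_design(records: pd.DataFrame) -> pd.DataFrame:
    """Derived (centred / indicator) covariate columns the hazard acts on."""
    m = COVARIATE_MARGINALS
    age_c = (records["age"] - m["age_mean"]) / m["age_sd"]
    return pd.DataFrame(
        {
            "age_c": age_c,
            "age_c2": age_c**2 - 1.0,
            "female": (records["infant_sex"] == "female").astype(float),
            "race_black": (records["race"] == "Black").astype(float),
            "race_aian": (records["race"] == "AIAN").astype(float),
            "race_asian": (records["race"] == "AsianNHPI").astype(float),
            "race_multi": (records["race"] == "MultiOther").astype(float),
            "hispanic": records["hispanic"].astype(float),
            "poverty_c": (records["poverty_rate"] - 14.7) / 12.8,
            "bmi_c": (records["bmi"] - m["bmi_mean"]) / m["bmi_sd"],
            "tobacco": records["tobacco"].astype(float),
        },
        index=records.index,
    )


class DataError(ValueError):
    pass


def assign_outcomes(
    pregnancies: pd.DataFrame,
    cumexp: np.ndarray,
    hazard: HazardParams,
    seed: int,
    site_intercepts: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Draw delivery timing from the weekly discrete-time hazard.

    ``cumexp`` holds the chosen cumulative exposure metric at the start of
    each at-risk week: shape (n, 15) for weeks 22..36.  Each pregnancy passes
    through weekly Bernoulli trials; the first success sets delivery uniformly
    within that week; survivors draw a term gestational age from
    ``term_ga_distribution`` (uniform day within the drawn week).

    Returns a copy of ``pregnancies`` with ``ga_days``, ``preterm``,
    ``delivery_week`` and ``site_intercept`` columns.
    """
    n = len(pregnancies)
    cumexp = np.asarray(cumexp, dtype=float)
    if cumexp.shape != (n, len(RISK_WEEKS)):
        raise DataError(
            f"cumulative exposure must be (n, {len(RISK_WEEKS)}) for weeks 22..36; "
            f"got {cumexp.shape}"
        )
    if np.isnan(cumexp).any():
        raise DataError("missing cumulative exposure for an at-risk week")
    rng = np.random.default_rng(seed)

    sites = pregnancies["site_id"].to_numpy()
    if site_intercepts is None:
        uniq = pd.unique(sites)
        draws = rng.normal(0.0, hazard.sigma_site, size=len(uniq))
        site_intercepts = dict(zip(uniq, draws))
    b_site = np.array([site_intercepts[s] for s in sites])

    design = hazard_design(pregnancies)
    lin = b_site.copy()
    for name, beta in hazard.beta_covariates.items():
        if name not in design.columns:
            raise DataError(f"hazard covariate {name!r} not in design")
        lin += beta * design[name].to_numpy()

    delivery_week = np.full(n, -1, dtype=int)
    at_risk = np.ones(n, dtype=bool)
    for k, w in enumerate(RISK_WEEKS):
        eta = hazard.baseline_logit[k] + hazard.beta_exposure * cumexp[:, k] + lin
        p = expit(eta)
        hit = at_risk & (rng.random(n) < p)
        delivery_week[hit] = w
        at_risk &= ~hit

    ga = np.empty(n, dtype=int)
    preterm_mask = delivery_week > 0
    ga[preterm_mask] = 7 * delivery_week[preterm_mask] + rng.integers(0, 7, size=int(preterm_mask.sum()))
    n_term = int((~preterm_mask).sum())
    weeks = np.array(list(hazard.term_ga_distribution))
    probs = np.array(list(hazard.term_ga_distribution.values()))
    term_weeks = rng.choice(weeks, size=n_term, p=probs)
    ga[~preterm_mask] = 7 * term_weeks + rng.integers(0, 7, size=n_term)
    delivery_week[~preterm_mask] = ga[~preterm_mask] // 7

    out = pregnancies.copy()
    out["ga_days"] = ga
    out["delivery_week"] = delivery_week
    out["preterm"] = (ga < PRETERM_CUTOFF_DAYS).astype(int)
    out["site_intercept"] = b_site
    out.attrs["seed"] = seed
    out.attrs["site_intercepts"] = dict(site_intercepts)
    return out


def inject_missingness(
    records: pd.DataFrame, spec: Sequence[MissingnessRule], seed: int
) -> pd.DataFrame:
    """Mask covariate cells per the missingness rules.

    Exposure and outcome columns are never masked; a MAR rule may condition
    only on a column no rule masks."""
    protected = {"pregnancy_id", "site_id", "tract_id", "conception_date",
                 "ga_days", "preterm", "delivery_week"}
    masked_vars = {r.variable for r in spec if r.mechanism != "none"}
    out = records.copy()
    rng = np.random.default_rng(seed)
    for rule in spec:
        if rule.mechanism == "none":
            continue
        if rule.variable in protected:
            raise ParameterError(f"may not mask {rule.variable!r}")
        if rule.variable not in out.columns:
            raise ParameterError(f"unknown covariate {rule.variable!r}")
        if rule.mechanism == "MCAR":
            mask = rng.random(len(out)) < rule.rate
        else:  # MAR
            if rule.depends_on in masked_vars:
                raise ParameterError(
                    f"MAR rule for {rule.variable!r} conditions on masked "
                    f"column {rule.depends_on!r}"
                )
            rates = out[rule.depends_on].map(rule.rate_by_level)
            if rates.isna().any():
                raise ParameterError(
                    f"rate_by_level missing a level of {rule.depends_on!r}"
                )
            mask = rng.random(len(out)) < rates.to_numpy(dtype=float)
        col = out[rule.variable]
        if col.dtype.kind in "iu":
            out[rule.variable] = col.astype(float)
        out.loc[mask, rule.variable] = np.nan
    return out


#: Masking rates echoing the cohort's printed covariate missingness.
TABLE1_MISSINGNESS = (
    MissingnessRule("age", "MCAR", 0.003),
    MissingnessRule("race", "MCAR", 0.069),
    MissingnessRule("hispanic", "MCAR", 0.021),
    MissingnessRule("education", "MCAR", 0.137),
    MissingnessRule("parity", "MCAR", 0.142),
    MissingnessRule("bmi", "MCAR", 0.122),
    MissingnessRule("tobacco", "MCAR", 0.122),
    MissingnessRule("alcohol", "MCAR", 0.184),
    MissingnessRule("poverty_rate", "MCAR", 0.005),
)


# ---------------------------------------------------------------------------
# one-call cohort bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Everything one simulated study produces, ready for the pipeline."""

    config: CohortConfig
    exposure_params: ExposureProcessParams
    hazard: HazardParams
    sites: pd.DataFrame
    tracts: pd.DataFrame
    series: dict[str, DailySeries]
    pregnancies: pd.DataFrame       # with outcomes
    residence: pd.DataFrame
    exposure_matrix: np.ndarray     # daily, NaN past delivery
    metrics: pd.DataFrame           # one row per pregnancy
    weekly: pd.DataFrame            # week-specific smoke days
    cumulative: pd.DataFrame        # cumulative-at-start-of-week metrics


def simulate_cohort(
    config: CohortConfig | None = None,
    exposure_params: ExposureProcessParams | None = None,
    hazard: HazardParams | None = None,
) -> SyntheticCohort:
    """Simulate a full synthetic study under the default calibrated settings.

    Deterministic given ``config.seed``: series, pregnancies and outcomes use
    independent child seeds spawned from it.
    """
    config = config or CohortConfig()
    exposure_params = exposure_params or ExposureProcessParams()
    hazard = hazard or HazardParams()

    root = np.random.SeedSequence(config.seed)
    s_sites, s_series, s_outcome, s_missing = [
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(4)
    ]
    rng = np.random.default_rng(s_sites)
    preg, residence, sites, tracts = simulate_pregnancies(config, exposure_params, rng=rng)

    series_start = config.conception_start - timedelta(days=35)
    series_end = config.conception_end + timedelta(days=301)
    store = simulate_series_store(exposure_params, tracts, series_start, series_end, s_series)

    # daily exposure through the longest possible gestation (42w6d = 300 days)
    preg_full = preg.assign(ga_days=300)
    from .exposure import cohort_exposure_matrix

    matrix = cohort_exposure_matrix(preg_full, residence, store, n_days=300)
    cum = cohort_cumulative_table(matrix, preg["pregnancy_id"], weeks=RISK_WEEKS)
    metric_col = hazard.exposure_metric
    cumexp = (
        cum.pivot(index="pregnancy_id", columns="week", values=metric_col)
        .loc[preg["pregnancy_id"], list(RISK_WEEKS)]
        .to_numpy(dtype=float)
    )
    preg = assign_outcomes(preg, cumexp, hazard, s_outcome)

    # truncate daily exposure at delivery
    ga = preg["ga_days"].to_numpy()
    cols = np.arange(matrix.shape[1])
    matrix = np.where(cols[None, :] < ga[:, None], matrix, np.nan)

    metrics = cohort_metrics_table(matrix, preg["pregnancy_id"])
    weekly = cohort_weekly_table(matrix, preg["pregnancy_id"])
    cumulative = cohort_cumulative_table(matrix, preg["pregnancy_id"])

    if config.include_confounders:
        conf = simulate_confounder_series(tracts, series_start, series_end, s_series + 1)
        temp = np.empty(len(preg))
        apm = np.empty(len(preg))
        for i, row in enumerate(preg.itertuples(index=False)):
            df = conf[str(row.tract_id)]
            c = pd.Timestamp(row.conception_date)
            sl = df.loc[c : c + pd.Timedelta(days=int(row.ga_days) - 1)]
            temp[i] = sl["temperature"].mean()
            apm[i] = sl["ambient_pm25"].mean()
        preg["avg_temperature"] = temp
        preg["avg_ambient_pm25"] = apm

    if config.missingness_spec:
        preg = inject_missingness(preg, config.missingness_spec, s_missing)

    for df in (metrics, weekly, cumulative):
        df.attrs["seed"] = config.seed
    return SyntheticCohort(
        config=config, exposure_params=exposure_params, hazard=hazard,
        sites=sites, tracts=tracts, series=store, pregnancies=preg,
        residence=residence, exposure_matrix=matrix, metrics=metrics,
        weekly=weekly, cumulative=cumulative,
    )
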