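"""Cohort inclusion rules and person-period expansion.

The analysis cohort keeps live singleton births conceived inside the study
window and at least 41 weeks (287 days) before the end of exposure coverage,
so that every included pregnancy could have been observed to term — the
restriction that prevents fixed cohort bias (a cohort truncated in calendar
time otherwise preferentially captures short, i.e. preterm, pregnancies near
the end of the window).

The included cohort is then expanded to the person-period table for pooled
logistic regression: one row per pregnancy and at-risk gestational week
22..36, with the event indicator set in the delivery week for preterm births
and term births (>= 37 completed weeks, GA >= 259 days) censored at week 36.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .exposure import PRETERM_CUTOFF_DAYS

FIXED_COHORT_DAYS = 287  # 41 weeks
MIN_GA_DAYS = 154        # 22 completed weeks


@dataclass(frozen=True)
class InclusionRules:
    """Configurable inclusion thresholds (defaults follow the study design)."""

    conception_start: date = date(2006, 1, 1)
    conception_end: date = date(2020, 3, 20)
    require_singleton: bool = True
    min_ga_days: int = MIN_GA_DAYS


def apply_inclusion_rules(
    records: pd.DataFrame,
    exposure_end_date: date,
    rules: InclusionRules | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the birth-level inclusion rules in order.

    Rules (applied disjointly, first failure wins):

    1. ``unparseable`` — missing/unparseable conception date or gestational age;
    2. ``multiple_gestation`` — plurality > 1;
    3. ``conception_outside_window`` — conception before the window start;
    4. ``fixed_cohort_bias`` — conceived fewer than 41 weeks before the end of
       exposure coverage (``conception + 287 > exposure_end + 1`` half-open);
    5. ``conception_outside_window`` — conception after the window end, when
       that end is earlier than the fixed-cohort cutoff;
    6. ``ga_below_22_weeks`` — gestational age under 154 days.

    The fixed-cohort rule precedes the window-upper check because the study
    window's upper bound is itself derived from the 41-week restriction; with
    the default dates the two coincide and the exclusion is attributed to
    fixed cohort bias.

    Returns ``(included records, exclusion ledger)``; ledger counts sum to
    ``len(records) - len(included)``.
    """
    rules = rules or InclusionRules()
    ledger = {
        "unparseable": 0,
        "multiple_gestation": 0,
        "conception_outside_window": 0,
        "fixed_cohort_bias": 0,
        "ga_below_22_weeks": 0,
    }
    conception = pd.to_datetime(records["conception_date"], errors="coerce")
    ga = pd.to_numeric(records.get("ga_days"), errors="coerce")

    bad = conception.isna() | ga.isna()
    ledger["unparseable"] = int(bad.sum())
    keep = ~bad

    if rules.require_singleton and "plurality" in records.columns:
        multi = keep & (pd.to_numeric(records["plurality"], errors="coerce").fillna(1) > 1)
        ledger["multiple_gestation"] = int(multi.sum())
        keep &= ~multi

    start = pd.Timestamp(rules.conception_start)
    end = pd.Timestamp(rules.conception_end)
    early = keep & (conception < start)
    ledger["conception_outside_window"] = int(early.sum())
    keep &= ~early

    cutoff = pd.Timestamp(exposure_end_date + timedelta(days=1)) - pd.Timedelta(days=FIXED_COHORT_DAYS)
    late = keep & (conception > cutoff)
    ledger["fixed_cohort_bias"] = int(late.sum())
    keep &= ~late

    outside = keep & (conception > end)
    ledger["conception_outside_window"] += int(outside.sum())
    keep &= ~outside

    short = keep & (ga < rules.min_ga_days)
    ledger["ga_below_22_weeks"] = int(short.sum())
    keep &= ~short

    return records.loc[keep].copy(), ledger


def apply_site_exclusions(
    records: pd.DataFrame,
    covariates: list[str],
    min_births: int = 100,
    max_missing: float = 0.25,
    flagged_sites: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop whole study sites that cannot support the primary model.

    A site is excluded when it has fewer than ``min_births`` included births,
    when any listed covariate exceeds ``max_missing`` missingness within the
    site, or when it is flagged (metadata) as having recruited on low
    gestational age or birthweight.  Returns ``(records, site ledger)``; the
    ledger has one row per site with reasons and counts.  An empty result is
    permitted (a warning is attached via ``attrs``).
    """
    flagged_sites = flagged_sites or set()
    rows = []
    keep_sites = []
    for site, g in records.groupby("site_id", sort=True):
        reasons = []
        if site in flagged_sites:
            reasons.append("selection_on_outcome")
        if len(g) < min_births:
            reasons.append("too_few_births")
        worst = 0.0
        for c in covariates:
            if c in g.columns:
                worst = max(worst, float(g[c].isna().mean()))
        if worst > max_missing:
            reasons.append("covariate_missingness")
        rows.append(
            {
                "site_id": site,
                "n_births": len(g),
                "max_covariate_missingness": worst,
                "excluded": bool(reasons),
                "reasons": ";".join(reasons),
            }
        )
        if not reasons:
            keep_sites.append(site)
    ledger = pd.DataFrame(rows)
    out = records[records["site_id"].isin(keep_sites)].copy()
    if out.empty:
        out.attrs["warning"] = "all sites excluded"
    return out, ledger


def person_period_expand(
    records: pd.DataFrame,
    cumulative: pd.DataFrame,
    exposure_columns: list[str] | None = None,
    covariate_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Expand births into one row per at-risk gestational week (22..36).

    ``cumulative`` is the long cumulative-at-start-of-week table
    (pregnancy_id, week, cum_*) from the exposure stage; "start of week w"
    exposure covers days 0..7w-1, so the outcome week's own exposure never
    enters its row (no exposure-after-event leakage).

    Row count per pregnancy is ``min(GA // 7, 36) - 21``; for a preterm birth
    delivered in week w* the event indicator is 1 exactly in week w*, term
    births (GA >= 259 days) contribute weeks 22..36 all with event 0.

    Records with GA < 154 days are dropped and reported under
    ``table.attrs["exclusions"]``.  Re-expanding an already expanded table is
    rejected.
    """
    if {"gestational_week", "event"}.issubset(records.columns):
        raise ValueError("input looks already person-period expanded")
    ga = records["ga_days"].to_numpy(dtype=int)
    short = ga < MIN_GA_DAYS
    n_short = int(short.sum())
    recs = records.loc[~short]
    ga = ga[~short]

    last_week = np.minimum(ga // 7, 36)
    n_rows = last_week - 21
    idx = np.repeat(np.arange(len(recs)), n_rows)
    week = np.concatenate([np.arange(22, lw + 1) for lw in last_week]) if len(recs) else np.array([], int)

    preterm = (ga < PRETERM_CUTOFF_DAYS).astype(int)
    event = np.zeros(len(week), dtype=int)
    # event fires in the delivery week of preterm births only
    ends = np.cumsum(n_rows) - 1
    ev_rows = ends[preterm.astype(bool)]
    event[ev_rows] = 1

    if covariate_columns is None:
        covariate_columns = [
            c for c in recs.columns
            if c not in ("ga_days", "delivery_week", "preterm")
        ]
    table = recs.iloc[idx][covariate_columns].reset_index(drop=True)
    table.insert(1, "gestational_week", week)
    table["event"] = event
    table["weight"] = 1.0  # analysis weights reserved

    cum = cumulative.rename(columns={"week": "gestational_week"})
    if exposure_columns is not None:
        cum = cum[["pregnancy_id", "gestational_week"] + exposure_columns]
    before = len(table)
    table = table.merge(cum, on=["pregnancy_id", "gestational_week"], how="left", sort=False)
    if len(table) != before:
        raise ValueError("cumulative table has duplicate (pregnancy, week) rows")
    exp_cols = [c for c in table.columns if c.startswith("cum_")]
    missing = table[exp_cols].isna().any(axis=1) if exp_cols else pd.Series(False, index=table.index)
    if missing.any():
        pid = table.loc[missing, "pregnancy_id"].iloc[0]
        w = table.loc[missing, "gestational_week"].iloc[0]
        raise ValueError(f"missing cumulative exposure for pregnancy {pid} at week {w}")

    table.attrs["exclusions"] = {"ga_below_22_weeks": n_short}
    table.attrs["n_pregnancies"] = len(recs)
    table.attrs["n_events"] = int(preterm.sum())
    return table
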