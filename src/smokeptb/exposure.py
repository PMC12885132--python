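"""Pregnancy wildfire-PM2.5 exposure metrics.

Turns census-tract daily wildfire PM2.5 series plus a residential history into
the per-pregnancy exposure summaries used throughout the analysis:

* mean daily wildfire PM2.5 over the exposure period,
* smoke days — days whose daily mean exceeds a threshold (>0 strictly, or
  >= 2.5 / 5.0 / 10.0 µg/m³),
* smoke waves — runs of consecutive smoke days lasting at least 2, 3 or 4 days,
* week-specific smoke-day counts (gestational weeks 0–35),
* cumulative metrics from conception to the start of each gestational week,
* trimester summaries.

Gestational time convention: day 0 is conception; gestational week ``w`` spans
days ``[7w, 7w+6]``; "start of week w" means exposure over days ``0..7w-1``.

A "wave of duration d" is a maximal run of length >= d, so a 5-day run
contributes one wave to each of d = 2, 3 and >=4.  This at-least-d convention
makes wave prevalence monotone non-increasing in duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Smoke-day thresholds, µg/m³.  0.0 is evaluated strictly (> 0), the rest
#: inclusively (>= t), matching how exceedance days are defined.
THRESHOLDS: tuple[float, ...] = (0.0, 2.5, 5.0, 10.0)
WAVE_THRESHOLDS: tuple[float, ...] = (2.5, 5.0, 10.0)
WAVE_DURATIONS: tuple[int, ...] = (2, 3, 4)

PRETERM_CUTOFF_DAYS = 259  # 37 completed weeks


def _threshold_key(t: float) -> str:
    if t == 0.0:
        return "gt0"
    return "ge" + ("%g" % t).replace(".", "p")


def threshold_column(t: float, prefix: str = "days") -> str:
    """Column name for a threshold, e.g. ``days_gt0``, ``days_ge2p5``."""
    return f"{prefix}_{_threshold_key(t)}"


class LinkageError(ValueError):
    """A pregnancy day could not be assigned a tract exposure value."""


@dataclass(frozen=True)
class DailySeries:
    """One census tract's gap-free daily wildfire PM2.5 series (µg/m³)."""

    tract_id: str
    start_date: date
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("daily series must be a non-empty 1-d vector")
        if np.any(v < 0) or np.any(~np.isfinite(v)):
            raise ValueError("daily PM2.5 values must be finite and >= 0")
        object.__setattr__(self, "values", v)

    @property
    def end_date(self) -> date:
        """Last covered calendar day (inclusive)."""
        return self.start_date + timedelta(days=len(self.values) - 1)

    def slice(self, start: date, n_days: int) -> np.ndarray:
        i0 = (start - self.start_date).days
        if i0 < 0 or i0 + n_days > len(self.values):
            raise LinkageError(
                f"tract {self.tract_id}: series does not cover "
                f"{start} .. {start + timedelta(days=n_days - 1)}"
            )
        return self.values[i0 : i0 + n_days]


@dataclass(frozen=True)
class ResidentialHistory:
    """Ordered, non-overlapping residence intervals, half-open [start, end)."""

    intervals: tuple[tuple[str, date, date], ...]

    def __post_init__(self) -> None:
        iv = tuple(self.intervals)
        if not iv:
            raise ValueError("residential history needs at least one interval")
        for tract, s, e in iv:
            if e <= s:
                raise ValueError(f"empty interval for tract {tract}: [{s}, {e})")
        for (_, _, e0), (_, s1, _) in zip(iv, iv[1:]):
            if s1 < e0:
                raise ValueError("residential intervals overlap")
        object.__setattr__(self, "intervals", iv)

    def tract_on(self, day: date, max_gap: int = 7) -> str:
        """Tract of residence on ``day``, carrying the previous tract forward
        across gaps of at most ``max_gap`` days."""
        last_tract = None
        last_end = None
        for tract, s, e in self.intervals:
            if s <= day < e:
                return tract
            if e <= day:
                last_tract, last_end = tract, e
        if last_tract is not None and (day - last_end).days < max_gap:
            return last_tract
        raise LinkageError(f"no residence covering {day} (max_gap={max_gap})")


def link_residence_series(
    history: ResidentialHistory,
    store: Mapping[str, DailySeries],
    conception: date,
    ga_days: int,
    max_gap: int = 7,
) -> np.ndarray:
    """Per-gestational-day exposure vector: day d takes the value of the tract
    of residence on ``conception + d``.

    Residence gaps up to ``max_gap`` days carry the last tract forward;
    longer gaps raise :class:`LinkageError` naming the date.
    """
    if ga_days <= 0:
        raise ValueError("ga_days must be positive")
    out = np.empty(ga_days, dtype=float)
    # group consecutive days by tract to slice series in blocks
    d = 0
    while d < ga_days:
        day = conception + timedelta(days=d)
        tract = history.tract_on(day, max_gap=max_gap)
        d1 = d + 1
        while d1 < ga_days and history.tract_on(conception + timedelta(days=d1), max_gap=max_gap) == tract:
            d1 += 1
        if tract not in store:
            raise LinkageError(f"no daily series for tract {tract}")
        out[d:d1] = store[tract].slice(day, d1 - d)
        d = d1
    return out


# ---------------------------------------------------------------------------
# counting primitives
# ---------------------------------------------------------------------------

def _exceed_mask(values: np.ndarray, threshold: float, strict: bool) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    return (values > threshold) if strict else (values >= threshold)


def count_smoke_days(values: Sequence[float], threshold: float, strict: bool | None = None) -> int:
    """Number of days whose value exceeds ``threshold``.

    ``strict=None`` applies the field convention: strictly greater for the
    0 µg/m³ threshold, at-or-above for positive thresholds.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("exposure vector must be non-empty")
    if strict is None:
        strict = threshold == 0.0
    return int(_exceed_mask(v, threshold, strict).sum())


def count_smoke_waves(values: Sequence[float], threshold: float, min_duration: int) -> int:
    """Number of maximal runs of consecutive exceedance days of length
    >= ``min_duration`` (an at-least-d wave; see module docstring)."""
    if min_duration not in (2, 3, 4):
        raise ValueError("min_duration must be 2, 3 or 4")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    v = np.asarray(values, dtype=float)
    if v.size < min_duration:
        return 0
    mask = _exceed_mask(v, threshold, strict=threshold == 0.0)
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    run_lengths = np.flatnonzero(d == -1) - np.flatnonzero(d == 1)
    return int((run_lengths >= min_duration).sum())


def week_specific_days(values: Sequence[float], threshold: float, week: int) -> int:
    """Smoke days within gestational week ``week`` (days 7w..7w+6).

    Only fully covered weeks are defined; a partial terminal week raises.
    """
    if not 0 <= week <= 35:
        raise ValueError("week must be in 0..35")
    v = np.asarray(values, dtype=float)
    if len(v) < 7 * (week + 1):
        raise ValueError(f"week {week} not fully covered by a {len(v)}-day vector")
    return count_smoke_days(v[7 * week : 7 * week + 7], threshold)


def cumulative_by_week(values: Sequence[float], weeks: Sequence[int] | None = None) -> pd.DataFrame:
    """Cumulative metrics from conception to the start of each gestational week.

    For week ``w`` the summaries cover days ``0..7w-1``.  Returns a frame
    indexed by week with ``cum_mean`` (µg/m³) and smoke-day counts per
    threshold (``cum_days_gt0`` etc.).  Weeks default to every complete week
    ``1..min(37, len(values)//7)``.
    """
    v = np.asarray(values, dtype=float)
    max_week = len(v) // 7
    if weeks is None:
        weeks = range(1, min(37, max_week) + 1)
    weeks = list(weeks)
    if not weeks:
        raise ValueError("no complete gestational week covered")
    for w in weeks:
        if w < 1 or 7 * w > len(v):
            raise ValueError(f"week {w} exceeds vector coverage ({len(v)} days)")
    rows = {}
    csum = np.concatenate(([0.0], np.cumsum(v)))
    cnt = {
        t: np.concatenate(([0], np.cumsum(_exceed_mask(v, t, t == 0.0).astype(int))))
        for t in THRESHOLDS
    }
    for w in weeks:
        d = 7 * w
        row = {"cum_mean": csum[d] / d}
        for t in THRESHOLDS:
            row[threshold_column(t, "cum_days")] = int(cnt[t][d])
        rows[w] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "week"
    return out


@dataclass
class ExposureMetrics:
    """Per-pregnancy exposure summary over one exposure period."""

    n_days: int
    mean_daily: float
    smoke_days: dict[float, int]
    smoke_waves: dict[tuple[float, int], int] = field(default_factory=dict)

    @classmethod
    def from_vector(cls, values: Sequence[float]) -> "ExposureMetrics":
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            return cls(n_days=0, mean_daily=float("nan"), smoke_days={t: 0 for t in THRESHOLDS})
        return cls(
            n_days=len(v),
            mean_daily=float(v.mean()),
            smoke_days={t: count_smoke_days(v, t) for t in THRESHOLDS},
            smoke_waves={
                (t, d): count_smoke_waves(v, t, d)
                for t in WAVE_THRESHOLDS
                for d in WAVE_DURATIONS
            },
        )


def trimester_metrics(values: Sequence[float]) -> dict[str, ExposureMetrics]:
    """Metrics per trimester: T1 = weeks 0–12, T2 = weeks 13–26, T3 = week 27
    to delivery.  A delivery before week 27 yields an empty (zero-day) T3."""
    v = np.asarray(values, dtype=float)
    bounds = {"T1": (0, 13 * 7), "T2": (13 * 7, 27 * 7), "T3": (27 * 7, len(v))}
    out = {}
    for name, (a, b) in bounds.items():
        out[name] = ExposureMetrics.from_vector(v[a:min(b, len(v))]) if a < len(v) else ExposureMetrics(
            n_days=0, mean_daily=float("nan"), smoke_days={t: 0 for t in THRESHOLDS}
        )
    return out


def threshold_percentiles(smoke_day_concentrations: Sequence[float]) -> dict[str, float]:
    """Empirical 50th/75th/90th percentiles (linear interpolation) of positive
    smoke-day concentrations — the basis for the 2.5/5.0/10.0 µg/m³ intensity
    thresholds."""
    x = np.asarray(smoke_day_concentrations, dtype=float)
    if x.size == 0:
        raise ValueError("empty smoke-day concentration sample")
    if np.any(x <= 0):
        raise ValueError("sample must contain positive smoke-day concentrations only")
    p50, p75, p90 = np.percentile(x, [50, 75, 90])
    return {"p50": float(p50), "p75": float(p75), "p90": float(p90)}


# ---------------------------------------------------------------------------
# cohort-level (vectorised) paths
# ---------------------------------------------------------------------------

def cohort_exposure_matrix(
    pregnancies: pd.DataFrame,
    residence: pd.DataFrame,
    store: Mapping[str, DailySeries],
    n_days: int | None = None,
    max_gap: int = 7,
) -> np.ndarray:
    """Daily exposure matrix, one row per pregnancy aligned at conception.

    ``pregnancies`` needs columns ``pregnancy_id, conception_date, ga_days``;
    ``residence`` is long (pregnancy_id, tract_id, start_date, end_date).
    Rows are padded with NaN beyond each pregnancy's gestational length.
    ``n_days`` (default: max ga_days) fixes the column count; if larger than a
    pregnancy's ga_days, extra days are NaN.
    """
    ga = pregnancies["ga_days"].to_numpy(dtype=int)
    if n_days is None:
        n_days = int(ga.max())
    n = len(pregnancies)
    mat = np.full((n, n_days), np.nan)

    # fast path: fill per residence interval with series slices
    series_vals = {t: s.values for t, s in store.items()}
    series_ord = {t: s.start_date.toordinal() for t, s in store.items()}
    conc_ord = np.array(
        [_as_date(d).toordinal() for d in pregnancies["conception_date"]], dtype=int
    )
    row_of = {pid: i for i, pid in enumerate(pregnancies["pregnancy_id"])}
    r_pid = residence["pregnancy_id"].to_numpy()
    r_tract = residence["tract_id"].astype(str).to_numpy()
    r_start = np.array([_as_date(d).toordinal() for d in residence["start_date"]], dtype=int)
    r_end = np.array([_as_date(d).toordinal() for d in residence["end_date"]], dtype=int)
    seen = np.zeros(n, dtype=bool)
    for k in range(len(residence)):
        i = row_of.get(r_pid[k])
        if i is None:
            continue
        seen[i] = True
        nd = min(int(ga[i]), n_days)
        a = max(r_start[k] - conc_ord[i], 0)
        b = min(r_end[k] - conc_ord[i], nd)
        if b <= a:
            continue
        tract = r_tract[k]
        if tract not in series_vals:
            raise LinkageError(f"no daily series for tract {tract}")
        c0 = conc_ord[i] - series_ord[tract]
        vals = series_vals[tract]
        if c0 + a < 0 or c0 + b > len(vals):
            raise LinkageError(
                f"tract {tract}: series does not cover pregnancy days {a}..{b - 1} "
                f"of {r_pid[k]}"
            )
        mat[i, a:b] = vals[c0 + a : c0 + b]
    if not seen.all():
        missing = pregnancies["pregnancy_id"].to_numpy()[~seen]
        raise LinkageError(f"no residential history for pregnancy {missing[0]}")

    # gap policy: any uncovered pregnancy-day falls back to the interval scan
    # with carry-forward up to max_gap days
    res_by_preg = None
    for i in range(n):
        nd = min(int(ga[i]), n_days)
        hole = np.isnan(mat[i, :nd])
        if not hole.any():
            continue
        if res_by_preg is None:
            res_by_preg = {pid: g for pid, g in residence.groupby("pregnancy_id")}
        g = res_by_preg[pregnancies["pregnancy_id"].iloc[i]]
        hist = ResidentialHistory(
            tuple(
                (str(t), _as_date(s), _as_date(e))
                for t, s, e in zip(g["tract_id"], g["start_date"], g["end_date"])
            )
        )
        mat[i, :nd] = link_residence_series(
            hist, store, date.fromordinal(conc_ord[i]), nd, max_gap=max_gap
        )
    return mat


def _as_date(x) -> date:
    if isinstance(x, date) and not isinstance(x, pd.Timestamp):
        return x
    return pd.Timestamp(x).date()


def cohort_metrics_table(matrix: np.ndarray, pregnancy_ids: Sequence) -> pd.DataFrame:
    """One-row-per-pregnancy exposure metrics over the full pregnancy.

    NaN padding (days past delivery) is ignored.  Columns: n_days, mean_daily,
    days_* per threshold, waves_<thr>_<dur> per (threshold, duration)."""
    valid = ~np.isnan(matrix)
    n_days = valid.sum(axis=1)
    filled = np.where(valid, matrix, 0.0)
    out = pd.DataFrame({"pregnancy_id": list(pregnancy_ids)})
    out["n_days"] = n_days
    with np.errstate(invalid="ignore"):
        out["mean_daily"] = filled.sum(axis=1) / n_days
    for t in THRESHOLDS:
        mask = _mask2d(matrix, t)
        out[threshold_column(t)] = mask.sum(axis=1)
    for t in WAVE_THRESHOLDS:
        mask = _mask2d(matrix, t)
        runs = _run_length_ends(mask)
        for d in WAVE_DURATIONS:
            out[f"waves_{_threshold_key(t)}_d{d}"] = (runs >= d).sum(axis=1)
    return out


def _mask2d(matrix: np.ndarray, t: float) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        if t == 0.0:
            return np.nan_to_num(matrix, nan=0.0) > 0.0
        return np.nan_to_num(matrix, nan=-1.0) >= t


def _run_length_ends(mask: np.ndarray) -> np.ndarray:
    """Per-cell value = run length at the last cell of each maximal run of True,
    0 elsewhere.  Lets callers count runs >= d as (result >= d).sum(axis=1)."""
    n, m = mask.shape
    lengths = np.zeros((n, m), dtype=np.int32)
    run = np.zeros(n, dtype=np.int32)
    for j in range(m):
        run = np.where(mask[:, j], run + 1, 0)
        lengths[:, j] = run
    # keep only run ends: cell j is a run end if mask[j] and not mask[j+1]
    ends = mask.copy()
    ends[:, :-1] &= ~mask[:, 1:]
    return np.where(ends, lengths, 0)


def cohort_weekly_table(matrix: np.ndarray, pregnancy_ids: Sequence) -> pd.DataFrame:
    """Long table of week-specific smoke-day counts (weeks 0..35), one row per
    pregnancy × fully-covered gestational week."""
    n, m = matrix.shape
    frames = []
    max_week = min(36, m // 7)
    valid = ~np.isnan(matrix)
    for w in range(max_week):
        sl = slice(7 * w, 7 * w + 7)
        full = valid[:, sl].all(axis=1)
        if not full.any():
            continue
        rows = {"pregnancy_id": np.asarray(pregnancy_ids)[full], "week": w}
        for t in THRESHOLDS:
            rows[threshold_column(t)] = _mask2d(matrix[full, sl], t).sum(axis=1)
        frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)


def cohort_cumulative_table(
    matrix: np.ndarray, pregnancy_ids: Sequence, weeks: Sequence[int] | None = None
) -> pd.DataFrame:
    """Long table of cumulative metrics at the start of each gestational week
    (days 0..7w-1), including cumulative smoke-wave counts.

    Weeks default to 1..37; each pregnancy contributes the weeks it fully
    covers."""
    n, m = matrix.shape
    if weeks is None:
        weeks = range(1, min(37, m // 7) + 1)
    weeks = list(weeks)
    valid = ~np.isnan(matrix)
    filled = np.where(valid, matrix, 0.0)
    csum = np.concatenate([np.zeros((n, 1)), np.cumsum(filled, axis=1)], axis=1)
    ccnt = {
        t: np.concatenate(
            [np.zeros((n, 1), dtype=int), np.cumsum(_mask2d(matrix, t), axis=1)], axis=1
        )
        for t in THRESHOLDS
    }
    cwave = {}
    for t in WAVE_THRESHOLDS:
        ends = _run_length_ends(_mask2d(matrix, t))
        for d in WAVE_DURATIONS:
            cwave[(t, d)] = np.concatenate(
                [np.zeros((n, 1), dtype=int), np.cumsum(ends >= d, axis=1)], axis=1
            )
    n_valid = np.concatenate(
        [np.zeros((n, 1), dtype=int), np.cumsum(valid, axis=1)], axis=1
    )
    frames = []
    ids = np.asarray(pregnancy_ids)
    for w in weeks:
        dcol = 7 * w
        if dcol > m:
            continue
        covered = n_valid[:, dcol] == dcol
        if not covered.any():
            continue
        rows = {
            "pregnancy_id": ids[covered],
            "week": w,
            "cum_mean": csum[covered, dcol] / dcol,
        }
        for t in THRESHOLDS:
            rows[threshold_column(t, "cum_days")] = ccnt[t][covered, dcol]
        for (t, d), arr in cwave.items():
            rows[f"cum_waves_{_threshold_key(t)}_d{d}"] = arr[covered, dcol]
        frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)


def series_store_to_frame(store: Mapping[str, DailySeries]) -> pd.DataFrame:
    """Long tract-day table (tract_id, date, pm25_wf) for CSV/Parquet export."""
    frames = []
    for tract_id, s in store.items():
        frames.append(
            pd.DataFrame(
                {
                    "tract_id": tract_id,
                    "date": pd.date_range(s.start_date, periods=len(s.values)),
                    "pm25_wf": s.values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def series_store_from_frame(df: pd.DataFrame) -> dict[str, DailySeries]:
    """Inverse of :func:`series_store_to_frame`; expects gap-free per-tract
    dates."""
    out = {}
    for tract_id, g in df.groupby("tract_id"):
        g = g.sort_values("date")
        dates = pd.to_datetime(g["date"])
        if len(g) > 1 and not (dates.diff().dropna() == pd.Timedelta(days=1)).all():
            raise ValueError(f"tract {tract_id}: daily series has gaps")
        out[str(tract_id)] = DailySeries(
            tract_id=str(tract_id),
            start_date=dates.iloc[0].date(),
            values=g["pm25_wf"].to_numpy(float),
        )
    return out


def correlation_diagnostics(metrics: pd.DataFrame, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Pearson correlation matrix across exposure metrics (or weekly counts).

    Zero-variance columns yield NaN correlations and are reported, not dropped.
    Requires at least 3 rows."""
    if len(metrics) < 3:
        raise ValueError("need at least 3 pregnancies for correlations")
    cols = list(columns) if columns is not None else [
        c for c in metrics.columns if metrics[c].dtype.kind in "fi" and c != "pregnancy_id"
    ]
    return metrics[cols].corr(method="pearson")
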