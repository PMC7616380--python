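"""Quality control of raw ground-monitor observations.

Raw hourly concentrations (μg/m³) from multiple monitoring networks are
turned into representative daily averages through four screens:

1. physical-bounds outlier removal (negative values and implausible
   spikes; the bounds are configurable and every rejection is logged);
2. hourly→daily aggregation keeping only days with at least 75 %
   completeness (>= 18 of 24 hourly values by default);
3. monitor coverage filters — monitor-months with fewer than 9 daily
   records are dropped, then monitor-years with fewer than 270 remaining
   daily records are dropped entirely;
4. cross-network deduplication of co-located monitors reporting identical
   co-occurring series, keeping the monitor with the most observations
   (network priority breaks full ties).

Days are naive calendar days in local standard time; no DST handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Monitor",
    "OutlierRules",
    "remove_outliers",
    "aggregate_hourly_to_daily",
    "filter_monitor_coverage",
    "deduplicate_monitors",
]

POLLUTANTS = ("NO2", "PM10", "PM25")

#: monitor classification: traffic + industrial sites -> hotspot,
#: rural + suburban sites -> background
MONITOR_TYPES = ("hotspot", "background")


@dataclass(frozen=True)
class Monitor:
    """A fixed measuring site in projected planar coordinates (metres)."""

    id: str
    network: str
    x: float
    y: float
    type: str

    def __post_init__(self) -> None:
        if self.type not in MONITOR_TYPES:
            raise ValueError(f"monitor type must be one of {MONITOR_TYPES}, got {self.type!r}")


@dataclass(frozen=True)
class OutlierRules:
    """Physical-plausibility bounds for hourly concentrations (μg/m³)."""

    lower: float = 0.0
    upper: float = 1000.0
    per_pollutant_upper: dict = field(default_factory=dict)

    def bounds(self, pollutant: str) -> tuple[float, float]:
        return self.lower, float(self.per_pollutant_upper.get(pollutant, self.upper))


def remove_outliers(
    hourly: pd.DataFrame, rules: OutlierRules = OutlierRules()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop hourly values outside the configured physical bounds.

    Parameters
    ----------
    hourly : DataFrame with columns ``monitor_id, time, pollutant, value``.
    rules : bounds configuration.

    Returns
    -------
    (kept, rejected) — ``rejected`` carries a ``reason`` column.
    """
    if hourly.empty:
        return hourly.copy(), hourly.assign(reason=pd.Series(dtype=str))
    values = pd.to_numeric(hourly["value"])
    lo = np.full(len(hourly), rules.lower)
    hi = np.array([rules.bounds(p)[1] for p in hourly["pollutant"]])
    below = values < lo
    above = values > hi
    bad = below | above | values.isna()
    rejected = hourly.loc[bad].copy()
    reason = np.where(below[bad], "below_lower_bound",
                      np.where(above[bad], "above_upper_bound", "non_numeric"))
    rejected["reason"] = reason
    return hourly.loc[~bad].copy(), rejected


def aggregate_hourly_to_daily(hourly: pd.DataFrame, min_hours: int = 18) -> pd.DataFrame:
    """Aggregate hourly values to daily means with a completeness rule.

    A day is kept only if at least ``min_hours`` of its 24 hourly slots
    carry a retained value (default 18, i.e. 75 % completeness).  One
    pollutant per call.

    Returns a DataFrame of daily records with columns
    ``monitor_id, date, pollutant, value, n_hours``.
    """
    if hourly.empty:
        return pd.DataFrame(columns=["monitor_id", "date", "pollutant", "value", "n_hours"])
    pollutants = hourly["pollutant"].unique()
    if len(pollutants) != 1:
        raise ValueError(f"one pollutant per call, got {sorted(pollutants)}")
    times = pd.to_datetime(hourly["time"])
    key = pd.DataFrame({
        "monitor_id": hourly["monitor_id"].to_numpy(),
        "hour": times.dt.floor("h").to_numpy(),
    })
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0]
        raise ValueError(
            f"duplicate (monitor, hour) entries, e.g. monitor {dup['monitor_id']} at {dup['hour']}"
        )
    df = pd.DataFrame({
        "monitor_id": key["monitor_id"],
        "date": key["hour"].dt.normalize(),
        "value": pd.to_numeric(hourly["value"]).to_numpy(),
    })
    agg = df.groupby(["monitor_id", "date"], sort=True)["value"].agg(["mean", "size"]).reset_index()
    agg = agg[agg["size"] >= min_hours]
    out = agg.rename(columns={"mean": "value", "size": "n_hours"})
    out["pollutant"] = pollutants[0]
    return out[["monitor_id", "date", "pollutant", "value", "n_hours"]].reset_index(drop=True)


def filter_monitor_coverage(
    daily: pd.DataFrame, min_per_month: int = 9, min_days_per_year: int = 270
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coverage screens applied per monitor (and pollutant), sequentially.

    First, monitor-months with fewer than ``min_per_month`` daily records
    are dropped; then monitor-years with fewer than ``min_days_per_year``
    remaining records are dropped entirely.  Idempotent.

    Returns (filtered, drop_log).
    """
    if daily.empty:
        return daily.copy(), pd.DataFrame(columns=["monitor_id", "pollutant", "period", "reason"])
    df = daily.copy()
    dates = pd.to_datetime(df["date"])
    df["_year"] = dates.dt.year
    df["_month"] = dates.dt.month
    keys = ["monitor_id", "pollutant", "_year"]

    month_counts = df.groupby(keys + ["_month"])["value"].transform("size")
    month_ok = month_counts >= min_per_month
    month_log = (
        df.loc[~month_ok, keys + ["_month"]]
        .drop_duplicates()
        .assign(reason="month_below_min")
    )
    df = df.loc[month_ok]

    year_counts = df.groupby(keys)["value"].transform("size")
    year_ok = year_counts >= min_days_per_year
    year_log = (
        df.loc[~year_ok, keys]
        .drop_duplicates()
        .assign(_month=np.nan, reason="year_below_min")
    )
    df = df.loc[year_ok]

    log = pd.concat([month_log, year_log], ignore_index=True)
    log["period"] = log["_year"].astype(str) + np.where(
        log["_month"].notna(), "-" + log["_month"].fillna(0).astype(int).astype(str).str.zfill(2), ""
    )
    log = log[["monitor_id", "pollutant", "period", "reason"]]
    return df.drop(columns=["_year", "_month"]).reset_index(drop=True), log


def _colocated_groups(monitors: list[Monitor], tol: float) -> list[list[Monitor]]:
    """Union-find grouping of monitors within ``tol`` metres of each other."""
    n = len(monitors)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = np.hypot(monitors[i].x - monitors[j].x, monitors[i].y - monitors[j].y)
            if d <= tol:
                parent[find(i)] = find(j)
    groups: dict[int, list[Monitor]] = {}
    for i, m in enumerate(monitors):
        groups.setdefault(find(i), []).append(m)
    return [g for g in groups.values() if len(g) > 1]


def deduplicate_monitors(
    daily: pd.DataFrame,
    monitors: list[Monitor],
    network_priority: list[str] | None = None,
    coloc_tol: float = 10.0,
    value_tol: float = 1e-6,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Remove redundant co-located monitors reporting identical series.

    Monitors within ``coloc_tol`` metres whose co-occurring observations
    agree within ``value_tol`` μg/m³ are duplicates: the one with most
    observations overall is kept.  On a full identical match (same dates,
    same values, same counts) the monitor of the highest-priority network
    is kept.  Co-located monitors with differing co-occurring values are
    both retained.

    Returns (filtered daily table, mapping dropped id -> kept id).
    """
    network_priority = network_priority or ["AURN", "AQE", "KCL", "SAQN", "WAQN"]

    def prio(net: str) -> int:
        return network_priority.index(net) if net in network_priority else len(network_priority)

    counts = daily.groupby("monitor_id")["value"].size()
    dropped: dict[str, str] = {}
    for group in _colocated_groups(monitors, coloc_tol):
        # greedy pairwise elimination inside each co-located group
        alive = sorted(group, key=lambda m: (-counts.get(m.id, 0), prio(m.network), m.id))
        survivors: list[Monitor] = []
        for cand in alive:
            is_dup = False
            for kept in survivors:
                a = daily[daily["monitor_id"] == kept.id]
                b = daily[daily["monitor_id"] == cand.id]
                merged = a.merge(b, on=["date", "pollutant"], suffixes=("_a", "_b"))
                if len(merged) and (merged["value_a"] - merged["value_b"]).abs().max() <= value_tol:
                    dropped[cand.id] = kept.id
                    is_dup = True
                    break
            if not is_dup:
                survivors.append(cand)
    if not dropped:
        return daily.copy(), dropped
    return daily[~daily["monitor_id"].isin(dropped)].reset_index(drop=True), dropped
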