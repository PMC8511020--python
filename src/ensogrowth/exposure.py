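"""Tropical-year ENSO exposure assignment and event-state classification.

The ENSO cycle typically develops in late boreal spring, peaks around the
turn of the calendar year, and decays the following spring.  Predictability
drops sharply across this boreal-spring transition (the "spring barrier"),
so a calendar-year exposure window would split single events across two
labels.  Exposure is therefore assigned by *tropical year* ``t``: May of
calendar year ``t`` through April of ``t + 1``.  The scalar exposure for
tropical year ``t`` is the mean of the eight monthly index values May–December
of ``t``; children interviewed January–April inherit the previous tropical
year's exposure.

A monthly sea-surface-temperature index (NINO3.4-style) is represented as a
:class:`pandas.DataFrame` with columns ``year``, ``month``, ``value`` —
contiguous months, no duplicates, finite values (see :func:`validate_nino`).

El Niño / La Niña state labels follow the Oceanic Niño Index convention:
anomalies relative to a monthly reference climatology, smoothed with a
centered 3-month rolling mean; a tropical year is El Niño (La Niña) if the
maximum (minimum) smoothed anomaly within the year exceeds +0.5 °C (falls
below −0.5 °C).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "validate_nino",
    "read_nino_csv",
    "assign_tropical_year",
    "tropical_year_mean",
    "tropical_year_means",
    "static_climatology",
    "moving_climatology",
    "anomaly_series",
    "classify_enso_state",
    "detrended_anomaly",
    "build_exposure_table",
]

MAY_DEC = tuple(range(5, 13))


def validate_nino(series: pd.DataFrame) -> pd.DataFrame:
    """Validate and sort a monthly index series.

    Requires columns ``year``, ``month``, ``value``; months must be in 1–12,
    contiguous (no gaps) once sorted, with no duplicate (year, month) and no
    non-finite values.  Returns the sorted frame (a copy).
    """
    required = {"year", "month", "value"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"index series missing columns: {sorted(missing)}")
    out = series[["year", "month", "value"]].copy()
    out["year"] = out["year"].astype(int)
    out["month"] = out["month"].astype(int)
    if ((out["month"] < 1) | (out["month"] > 12)).any():
        raise ValueError("month values must lie in 1..12")
    out = out.sort_values(["year", "month"], kind="mergesort").reset_index(drop=True)
    t = out["year"].to_numpy() * 12 + (out["month"].to_numpy() - 1)
    if len(np.unique(t)) != len(t):
        raise ValueError("duplicate (year, month) entries in index series")
    if len(t) > 1 and not np.all(np.diff(t) == 1):
        raise ValueError("index series has month gaps; must be contiguous")
    if not np.isfinite(out["value"].to_numpy()).all():
        raise ValueError("index series contains non-finite values")
    return out


def read_nino_csv(path) -> pd.DataFrame:
    """Read a monthly index CSV (year, month, value) and validate it."""
    return validate_nino(pd.read_csv(path))


def assign_tropical_year(year, month):
    """Map interview (year, month) to the tropical year supplying exposure.

    Months May–December belong to their own calendar year; January–April
    belong to the previous year's tropical year (pre-spring-barrier
    interviews inherit the prior event).  Accepts scalars or arrays.
    """
    y = np.asarray(year)
    m = np.asarray(month)
    if np.any((m < 1) | (m > 12)):
        raise ValueError("month must lie in 1..12")
    out = np.where(m >= 5, y, y - 1)
    if np.isscalar(year) or (out.ndim == 0):
        return int(out)
    return out


def tropical_year_mean(series: pd.DataFrame, t: int) -> float:
    """Mean index value over May–December of tropical year ``t``.

    All eight months must be present; a partial window raises rather than
    silently averaging fewer months.
    """
    series = validate_nino(series)
    sl = series[(series["year"] == t) & (series["month"] >= 5)]
    if len(sl) != 8:
        raise ValueError(
            f"tropical year {t}: need all 8 months May–December, found {len(sl)}"
        )
    return float(sl["value"].mean())


def tropical_year_means(series: pd.DataFrame) -> pd.Series:
    """May–December means for every tropical year with a complete window."""
    series = validate_nino(series)
    sub = series[series["month"].isin(MAY_DEC)]
    g = sub.groupby("year")["value"]
    full = g.count() == 8
    means = g.mean()[full]
    means.index.name = "tropical_year"
    means.name = "mean_may_dec"
    return means


def static_climatology(series: pd.DataFrame) -> pd.Series:
    """Per-calendar-month mean over the whole series (months 1..12)."""
    series = validate_nino(series)
    clim = series.groupby("month")["value"].mean()
    if len(clim) != 12:
        raise ValueError("climatology requires every calendar month present")
    return clim


def moving_climatology(
    series: pd.DataFrame, base_length: int = 30, step: int = 5
) -> pd.DataFrame:
    """Moving reference climatology in the NOAA CPC style.

    Years are grouped into ``step``-year blocks; each block's reference is
    the per-month mean over a ``base_length``-year window centered on the
    block (clipped to the available record).  Returns a frame with columns
    ``year``, ``month``, ``ref`` giving the reference mean applying to each
    (year, month) of the input.
    """
    series = validate_nino(series)
    years = np.arange(series["year"].min(), series["year"].max() + 1)
    by_month = series.pivot(index="year", columns="month", values="value")
    rows = []
    for y in years:
        block = (y - years[0]) // step
        center = years[0] + block * step + step // 2
        lo = center - base_length // 2
        hi = lo + base_length - 1
        # clip to the record, keeping the window length where possible
        lo = max(years[0], min(lo, years[-1] - base_length + 1))
        hi = min(years[-1], lo + base_length - 1)
        ref = by_month.loc[lo:hi].mean()
        for m in range(1, 13):
            if m in by_month.columns:
                rows.append((y, m, ref.get(m, np.nan)))
    return pd.DataFrame(rows, columns=["year", "month", "ref"])


def anomaly_series(series: pd.DataFrame, climatology) -> pd.DataFrame:
    """Subtract a monthly reference from the series.

    ``climatology`` is either a per-month mapping/Series (static, 12 entries)
    or a frame with columns (year, month, ref) as produced by
    :func:`moving_climatology`.
    """
    series = validate_nino(series)
    out = series.copy()
    if isinstance(climatology, pd.DataFrame):
        merged = out.merge(climatology, on=["year", "month"], how="left")
        if merged["ref"].isna().any():
            raise ValueError("climatology does not cover every (year, month)")
        out["value"] = merged["value"].to_numpy() - merged["ref"].to_numpy()
    else:
        clim = pd.Series(dict(climatology)) if isinstance(climatology, Mapping) else climatology
        if set(range(1, 13)) - set(clim.index):
            raise ValueError("static climatology must supply all 12 months")
        out["value"] = out["value"].to_numpy() - clim.reindex(out["month"]).to_numpy()
    return out


def classify_enso_state(
    series: pd.DataFrame,
    climatology,
    t: int,
    threshold: float = 0.5,
) -> str:
    """Label tropical year ``t`` as ``el_nino``, ``la_nina`` or ``neutral``.

    Anomalies (value − climatology) are smoothed with a centered 3-month
    rolling mean over the full series; windows centered on May ``t`` through
    April ``t + 1`` are inspected (edge centers borrow the adjacent month
    outside the tropical year when the record supplies it, and are dropped
    otherwise).  El Niño if the maximum exceeds ``+threshold``, La Niña if
    the minimum falls below ``−threshold``; if both, the larger absolute
    excursion wins.
    """
    anom = anomaly_series(series, climatology)
    vals = anom["value"].to_numpy()
    rolled = (
        pd.Series(vals).rolling(window=3, center=True, min_periods=3).mean().to_numpy()
    )
    tt = anom["year"].to_numpy() * 12 + (anom["month"].to_numpy() - 1)
    lo, hi = t * 12 + 4, (t + 1) * 12 + 3  # May t .. Apr t+1
    in_window = (tt >= lo) & (tt <= hi)
    if not in_window.any():
        raise ValueError(f"tropical year {t} not covered by the index series")
    window = rolled[in_window]
    window = window[np.isfinite(window)]
    if window.size == 0:
        raise ValueError(f"no complete 3-month windows inside tropical year {t}")
    mx, mn = window.max(), window.min()
    if mx > threshold and mn < -threshold:
        return "el_nino" if mx >= -mn else "la_nina"
    if mx > threshold:
        return "el_nino"
    if mn < -threshold:
        return "la_nina"
    return "neutral"


def detrended_anomaly(means: pd.Series) -> pd.Series:
    """OLS-detrended anomalies of tropical-year means.

    Residuals of ``mean_may_dec`` on a linear trend in tropical year, fitted
    over the supplied window.  Needs at least 3 years for a defined trend.
    """
    if len(means) < 3:
        raise ValueError("detrending needs at least 3 tropical years")
    x = means.index.to_numpy(dtype=float)
    y = means.to_numpy(dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    out = pd.Series(y - (slope * x + intercept), index=means.index)
    out.name = "detrended_anomaly"
    return out


def build_exposure_table(
    series: pd.DataFrame,
    climatology=None,
    threshold: float = 0.5,
    min_years_detrend: int = 10,
) -> pd.DataFrame:
    """Per-tropical-year exposure table.

    Columns: ``tropical_year``, ``mean_may_dec``, ``detrended_anomaly``,
    ``state``.  ``climatology`` defaults to the static per-month mean of the
    supplied series; pass the output of :func:`moving_climatology` for the
    moving-reference convention.
    """
    series = validate_nino(series)
    if climatology is None:
        climatology = static_climatology(series)
    means = tropical_year_means(series)
    if len(means) < min_years_detrend:
        raise ValueError(
            f"need at least {min_years_detrend} complete tropical years, have {len(means)}"
        )
    detr = detrended_anomaly(means)
    states = {}
    for t in means.index:
        try:
            states[t] = classify_enso_state(series, climatology, int(t), threshold)
        except ValueError:
            states[t] = "neutral"
    out = pd.DataFrame(
        {
            "tropical_year": means.index.to_numpy(),
            "mean_may_dec": means.to_numpy(),
            "detrended_anomaly": detr.to_numpy(),
            "state": [states[t] for t in means.index],
        }
    )
    return out
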