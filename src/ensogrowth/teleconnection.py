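"""Detection of ENSO teleconnections in gridded monthly climate fields.

A location is teleconnected when its local weather covaries reliably with
the equatorial-Pacific index at a short lag.  Detection is per calendar
month: for month ``m``, the pixel's month-``m`` values across years are
correlated with the index at month ``m − lag`` (default lag 2, crossing the
calendar-year boundary when needed).  A pixel is flagged when at least
``min_months`` of the 12 calendar months show a significant correlation
(two-sided Pearson, p < alpha), optionally restricted by sign.

Aggregation rules differ by variable, following the sample-definition
conventions of climate-health panel studies:

* a *country* is temperature-teleconnected when **at least 50%** of its
  population lives in flagged pixels (weak inequality);
* a first-level administrative unit has a *positive precipitation*
  teleconnection when **more than 50%** of its land area lies in pixels
  flagged with positively-signed significant correlations (strict
  inequality).

Because correlations are taken across years within a calendar month, mean
seasonality cancels by construction.  Shared slow warming/wetting trends
would still inflate correlations, so by default a linear year trend is
removed from both series month-by-month before correlating (``detrend=True``);
the p-value degrees of freedom account for the removed trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClimateGrid",
    "TeleconnectionMap",
    "monthly_lag_correlation",
    "significant_month_count",
    "pixel_teleconnected",
    "country_teleconnected",
    "admin_positive_precip",
    "build_teleconnection_map",
]


@dataclass
class ClimateGrid:
    """Monthly temperature/precipitation fields on a 0.5° pixel grid.

    ``pixels`` has one row per pixel with columns ``pixel``, ``lat``,
    ``lon``, ``country``, ``admin1``, ``population``, ``land_area``;
    ``years``/``months`` give the common time axis (length ``T``), and
    ``temperature``/``precipitation`` are ``(n_pixels, T)`` arrays.
    """

    pixels: pd.DataFrame
    years: np.ndarray
    months: np.ndarray
    temperature: np.ndarray
    precipitation: np.ndarray

    def __post_init__(self):
        need = {"pixel", "lat", "lon", "country", "admin1", "population", "land_area"}
        missing = need - set(self.pixels.columns)
        if missing:
            raise ValueError(f"pixel table missing columns: {sorted(missing)}")
        n, t = len(self.pixels), len(self.years)
        if len(self.months) != t:
            raise ValueError("years and months must have equal length")
        for name in ("temperature", "precipitation"):
            arr = getattr(self, name)
            if arr.shape != (n, t):
                raise ValueError(f"{name} must have shape (n_pixels, n_time) = ({n}, {t})")
        if (self.pixels["population"] < 0).any() or (self.pixels["land_area"] < 0).any():
            raise ValueError("population and land area must be non-negative")

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    def variable(self, name: str) -> np.ndarray:
        if name not in ("temperature", "precipitation"):
            raise ValueError("variable must be 'temperature' or 'precipitation'")
        return getattr(self, name)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format view (pixel, year, month, temperature, precipitation)."""
        n, t = self.temperature.shape
        return pd.DataFrame(
            {
                "pixel": np.repeat(self.pixels["pixel"].to_numpy(), t),
                "year": np.tile(self.years, n),
                "month": np.tile(self.months, n),
                "temperature": self.temperature.ravel(),
                "precipitation": self.precipitation.ravel(),
            }
        )

    def write_csv(self, values_path, pixels_path) -> None:
        self.to_long_frame().to_csv(values_path, index=False)
        self.pixels.to_csv(pixels_path, index=False)

    @classmethod
    def from_long_frame(cls, values: pd.DataFrame, pixels: pd.DataFrame) -> "ClimateGrid":
        values = values.sort_values(["pixel", "year", "month"], kind="mergesort")
        first = values[values["pixel"] == values["pixel"].iloc[0]]
        years = first["year"].to_numpy(dtype=int)
        months = first["month"].to_numpy(dtype=int)
        n = values["pixel"].nunique()
        pixels = pixels.sort_values("pixel").reset_index(drop=True)
        return cls(
            pixels=pixels,
            years=years,
            months=months,
            temperature=values["temperature"].to_numpy().reshape(n, -1),
            precipitation=values["precipitation"].to_numpy().reshape(n, -1),
        )

    @classmethod
    def read_csv(cls, values_path, pixels_path) -> "ClimateGrid":
        return cls.from_long_frame(pd.read_csv(values_path), pd.read_csv(pixels_path))


def _detrend_years(mat: np.ndarray, yrs: np.ndarray) -> np.ndarray:
    """Remove a linear trend in year from each row of ``mat`` (rows × years)."""
    x = yrs - yrs.mean()
    denom = float(x @ x)
    slope = (mat @ x) / denom
    return mat - mat.mean(axis=1, keepdims=True) - np.outer(slope, x)


def monthly_lag_correlation(
    grid: ClimateGrid,
    series: pd.DataFrame,
    variable: str = "temperature",
    lag: int = 2,
    detrend: bool = True,
):
    """Per-pixel, per-calendar-month Pearson correlation with the lagged index.

    For calendar month ``m``, pairs the pixel's month-``m`` value in year
    ``y`` with the index at total month ``12*y + (m-1) - lag``.  Returns
    ``(r, p, n)``: two ``(n_pixels, 12)`` arrays and the per-month pair
    counts (length 12).  Degenerate (zero-variance) pixel-months get
    ``r = p = nan`` and never count as significant.

    Requires an overlap of at least 10 years per month and ``lag >= 0``.
    """
    from .exposure import validate_nino

    if lag < 0:
        raise ValueError("lag must be non-negative")
    series = validate_nino(series)
    idx_t = series["year"].to_numpy() * 12 + (series["month"].to_numpy() - 1)
    idx_val = dict(zip(idx_t.tolist(), series["value"].tolist()))

    V = grid.variable(variable)
    n_pix = grid.n_pixels
    r = np.full((n_pix, 12), np.nan)
    p = np.full((n_pix, 12), np.nan)
    n_years = np.zeros(12, dtype=int)

    gt = grid.years * 12 + (grid.months - 1)
    for m in range(1, 13):
        cols = np.flatnonzero(grid.months == m)
        lag_t = gt[cols] - lag
        have = np.array([t in idx_val for t in lag_t])
        cols = cols[have]
        n = len(cols)
        n_years[m - 1] = n
        if n < 10:
            raise ValueError(
                f"calendar month {m}: only {n} overlapping years; need >= 10"
            )
        x = np.array([idx_val[t] for t in gt[cols] - lag], dtype=float)
        Y = V[:, cols].astype(float)
        yrs = grid.years[cols].astype(float)
        if detrend:
            xm = _detrend_years(x[None, :], yrs)[0]
            Ym = _detrend_years(Y, yrs)
            df = n - 3  # trend removal costs one further df
        else:
            xm = x - x.mean()
            Ym = Y - Y.mean(axis=1, keepdims=True)
            df = n - 2
        sx = np.sqrt(xm @ xm)
        sy = np.sqrt(np.einsum("ij,ij->i", Ym, Ym))
        with np.errstate(invalid="ignore", divide="ignore"):
            rm = (Ym @ xm) / (sy * sx)
        rm = np.clip(rm, -1.0, 1.0)
        degenerate = (sy == 0) | (sx == 0)
        rm[degenerate] = np.nan
        with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
            tstat = rm * np.sqrt(df / np.maximum(1.0 - rm**2, np.finfo(float).tiny))
        pm = 2.0 * stats.t.sf(np.abs(tstat), df)
        pm[degenerate] = np.nan
        r[:, m - 1] = rm
        p[:, m - 1] = pm
    return r, p, n_years


def significant_month_count(
    r: np.ndarray, p: np.ndarray, alpha: float = 0.05, sign: str = "any"
) -> np.ndarray:
    """Count per pixel the calendar months significant at ``alpha``.

    ``sign`` restricts to ``positive`` or ``negative`` correlations; NaN
    (degenerate) months never count.
    """
    if sign not in ("any", "positive", "negative"):
        raise ValueError("sign must be 'any', 'positive' or 'negative'")
    sig = np.asarray(p) < alpha
    if sign == "positive":
        sig &= np.asarray(r) > 0
    elif sign == "negative":
        sig &= np.asarray(r) < 0
    return np.nansum(sig, axis=-1).astype(int)


def pixel_teleconnected(
    r: np.ndarray,
    p: np.ndarray,
    min_months: int = 3,
    alpha: float = 0.05,
    sign: str = "any",
) -> np.ndarray:
    """Flag pixels with >= ``min_months`` significant months (sign-restricted)."""
    return significant_month_count(r, p, alpha=alpha, sign=sign) >= min_months


def country_teleconnected(
    flags: np.ndarray, pixels: pd.DataFrame, country
) -> bool:
    """Country flag: population-weighted share of flagged pixels >= 50%.

    Weak inequality — exactly half the population in flagged pixels counts.
    """
    sub = pixels["country"] == country
    if not sub.any():
        raise ValueError(f"unknown country {country!r}")
    pop = pixels.loc[sub, "population"].to_numpy(dtype=float)
    total = pop.sum()
    if total <= 0:
        raise ValueError(f"country {country!r} has zero total population")
    share = pop[np.asarray(flags)[sub.to_numpy()]].sum() / total
    return bool(share >= 0.5)


def admin_positive_precip(
    flags: np.ndarray, pixels: pd.DataFrame, admin1
) -> bool:
    """Admin-unit flag: land-area-weighted share of flagged pixels > 50%.

    Strict inequality — exactly half the area flagged does **not** qualify
    (this deliberately differs from the weak country rule).
    """
    sub = pixels["admin1"] == admin1
    if not sub.any():
        raise ValueError(f"unknown admin1 {admin1!r}")
    area = pixels.loc[sub, "land_area"].to_numpy(dtype=float)
    total = area.sum()
    if total <= 0:
        raise ValueError(f"admin1 {admin1!r} has zero land area")
    share = area[np.asarray(flags)[sub.to_numpy()]].sum() / total
    return bool(share > 0.5)


@dataclass
class TeleconnectionMap:
    """Pixel-, country- and admin-level teleconnection summary.

    ``pixel_table`` carries per-pixel significant-month counts and flags for
    temperature (any sign) and precipitation (positive sign); ``country_flags``
    maps country id → temperature-teleconnected; ``admin_pos_precip`` maps
    admin1 id → positive-precipitation flag.  ``params`` records the rule
    settings used.
    """

    pixel_table: pd.DataFrame
    country_flags: pd.Series
    admin_pos_precip: pd.Series
    params: dict = field(default_factory=dict)

    def teleconnected_countries(self) -> list:
        return sorted(self.country_flags.index[self.country_flags].tolist())

    def write_csv(self, pixel_path, country_path, admin_path) -> None:
        self.pixel_table.to_csv(pixel_path, index=False)
        self.country_flags.rename("teleconnected").rename_axis("country").reset_index().to_csv(
            country_path, index=False
        )
        self.admin_pos_precip.rename("pos_precip").rename_axis("admin1").reset_index().to_csv(
            admin_path, index=False
        )


def build_teleconnection_map(
    grid: ClimateGrid,
    series: pd.DataFrame,
    lag: int = 2,
    alpha: float = 0.05,
    min_months: int = 3,
    detrend: bool = True,
) -> TeleconnectionMap:
    """Run the full detection: correlations, pixel flags, country/admin rules."""
    r_t, p_t, _ = monthly_lag_correlation(grid, series, "temperature", lag, detrend)
    r_p, p_p, _ = monthly_lag_correlation(grid, series, "precipitation", lag, detrend)

    temp_count = significant_month_count(r_t, p_t, alpha, "any")
    temp_flag = temp_count >= min_months
    pos_count = significant_month_count(r_p, p_p, alpha, "positive")
    pos_flag = pos_count >= min_months
    neg_count = significant_month_count(r_p, p_p, alpha, "negative")

    pixel_table = grid.pixels[["pixel", "country", "admin1", "population", "land_area"]].copy()
    pixel_table["temp_sig_months"] = temp_count
    pixel_table["temp_teleconnected"] = temp_flag
    pixel_table["precip_pos_sig_months"] = pos_count
    pixel_table["precip_pos_flag"] = pos_flag
    pixel_table["precip_neg_sig_months"] = neg_count

    country_flags = pd.Series(
        {
            c: country_teleconnected(temp_flag, grid.pixels, c)
            for c in grid.pixels["country"].unique()
        }
    ).sort_index()
    admin_flags = pd.Series(
        {
            a: admin_positive_precip(pos_flag, grid.pixels, a)
            for a in grid.pixels["admin1"].unique()
        }
    ).sort_index()
    return TeleconnectionMap(
        pixel_table=pixel_table,
        country_flags=country_flags,
        admin_pos_precip=admin_flags,
        params={
            "lag": lag,
            "alpha": alpha,
            "min_months": min_months,
            "detrend": detrend,
        },
    )
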