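"""Synthetic world generator: index, climate grid, geography, survey microdata.

Every downstream stage of the pipeline (teleconnection detection, exposure
assignment, panel estimation, attribution) is validated against data with
*planted* ground truth.  This module builds all four input streams from one
seeded configuration:

* a monthly NINO3.4-style index — seasonal cycle plus an AR(1) anomaly whose
  innovation variance is phase-locked to peak around November–January;
* a 0.5° monthly temperature/precipitation grid in which each pixel loads on
  the 2-month-lagged index anomaly with a known coefficient (blocks of
  pixels with zero, positive and negative loadings are always present);
* a geography: pixels nest in first-level administrative units (admin1),
  admin1 in countries, countries in five world regions;
* child-level survey microdata whose anthropometric outcomes follow the
  panel model exactly — planted exposure coefficients, country-specific
  mother covariate effects, region trends and month effects, country×urban
  intercepts, and Gaussian child noise — with configurable fractions of
  quality-flagged and missing records.

The planted anthropometric effect operates only in countries given a nonzero
temperature loading (teleconnection is the causal pathway); the estimation
sample excludes non-teleconnected countries, so recovery is assessed where
the effect exists.

One integer seed makes every artifact bit-reproducible; independent
`numpy` ``SeedSequence`` streams keep the index, grid, nuisance parameters
and survey draws from perturbing one another when sizes change.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import exposure as expo
from .teleconnection import ClimateGrid, TeleconnectionMap

__all__ = [
    "NinoParams",
    "TeleParams",
    "EffectParams",
    "SurveyParams",
    "WorldConfig",
    "World",
    "simulate_nino",
    "simulate_climate_grid",
    "simulate_surveys",
    "build_geography",
    "ground_truth_teleconnection",
    "planted_parameters",
    "simulate_world",
    "write_ground_truth",
]

OUTCOMES = ("waz", "whz", "bmiz")


@dataclass
class NinoParams:
    """Index process: seasonal cycle + phase-locked AR(1) anomaly (°C)."""

    ar: float = 0.9
    innovation_sd: float = 0.45
    seasonal_amplitude: float = 0.3
    # innovation SD multiplier 1 + a*cos(2π(m−12)/12): peaks in December,
    # troughs in June — ENSO variance is largest around the year's end.
    phase_lock_amplitude: float = 0.5
    base_level: float = 0.0


@dataclass
class TeleParams:
    """Planted pixel loadings on the lag-2 index anomaly and noise scales."""

    temp_loading: float = 1.0  # °C per °C of index anomaly
    temp_noise_sd: float = 0.8
    precip_loading: float = 8.0  # mm per °C; sign assigned per admin block
    precip_noise_sd: float = 10.0
    precip_climatology: float = 80.0  # mm, base monthly total
    n_zero_countries: int = 4  # trailing countries with zero loadings
    pos_admin_fraction: float = 1.0 / 3.0  # admins per tele country with +precip


@dataclass
class EffectParams:
    """Planted panel-model coefficients for the child outcomes (σ-units).

    ``outcome_betas`` maps outcome → (β_n, β_p): the per-°C effect in areas
    with negative/neutral precipitation teleconnection and in positive-precip
    areas; the interaction coefficient is β_p − β_n.  Child noise is iid by
    default; ``year_shock_sd``/``admin_shock_sd`` plant common shocks at the
    clustering levels for variance-validation scenarios.
    """

    alpha: float = -0.931
    outcome_betas: dict = field(
        default_factory=lambda: {
            "waz": (-0.0251, 0.0482),
            "whz": (-0.0377, 0.0112),
            "bmiz": (-0.0381, -0.0011),
        }
    )
    gamma_edu: float = 0.02  # σ per year of mother's education
    gamma_age: float = 0.005  # σ per year of mother's age at birth
    region_trend_sd: float = 0.01  # σ/year, region slopes drawn N(0, sd)
    month_effect_sd: float = 0.05
    cell_intercept_sd: float = 0.3  # country×urban intercepts around alpha
    child_noise_sd: float = 0.3
    year_shock_sd: float = 0.0
    admin_shock_sd: float = 0.0
    tele_only: bool = True  # exposure effect only in teleconnected countries


@dataclass
class SurveyParams:
    """Survey-wave design: round-robin country rotation, cluster sampling."""

    n_children: int = 50_000
    survey_interval: int = 4  # years between waves for a given country
    clusters_per_wave: int = 25
    urban_share: float = 0.35
    weight_sigma: float = 0.3  # log-normal SD of cluster sampling weights
    flagged_fraction: float = 0.0056
    missing_fraction: float = 0.0057
    missing_mother_fraction: float = 0.002
    timing_depends_on_enso: bool = False


@dataclass
class WorldConfig:
    n_years: int = 33
    start_year: int = 1986
    n_countries: int = 20
    admin1_per_country: int = 6
    pixels_per_admin: int = 4
    n_regions: int = 5
    seed: int = 0
    nino: NinoParams = field(default_factory=NinoParams)
    tele: TeleParams = field(default_factory=TeleParams)
    effects: EffectParams = field(default_factory=EffectParams)
    survey: SurveyParams = field(default_factory=SurveyParams)

    def country_ids(self):
        return [f"C{c:02d}" for c in range(self.n_countries)]

    def region_of(self, c: int) -> str:
        return f"R{c % self.n_regions}"

    def admin_ids(self, c: int):
        return [f"C{c:02d}A{a}" for a in range(self.admin1_per_country)]


REGION_NAMES = None  # regions are labelled R0..R4; five, as in UNICEF groupings


def _rng(config: WorldConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def seasonal_cycle(config: WorldConfig) -> np.ndarray:
    """Deterministic monthly climatology of the index (months 1..12)."""
    m = np.arange(1, 13)
    p = config.nino
    return p.base_level + p.seasonal_amplitude * np.cos(2 * np.pi * (m - 4) / 12.0)


def simulate_nino(config: WorldConfig) -> pd.DataFrame:
    """Monthly index series over the simulation window.

    value(t) = seasonal_cycle(month) + a(t), with
    a(t) = ar·a(t−1) + s(month)·innovation_sd·z(t), where the multiplier
    s(m) = 1 + phase_lock_amplitude·cos(2π(m−12)/12) concentrates innovation
    variance in boreal winter.  A 10-year burn-in removes initial-condition
    dependence.  With innovation_sd = 0 the series is exactly the seasonal
    cycle.
    """
    if config.n_years < 10:
        raise ValueError("n_years must be at least 10")
    p = config.nino
    if not (0 <= p.ar < 1):
        raise ValueError("AR coefficient must lie in [0, 1) for stationarity")
    rng = _rng(config, 0)
    burn = 120
    total = burn + 12 * config.n_years
    months = (np.arange(total) % 12) + 1
    s = 1.0 + p.phase_lock_amplitude * np.cos(2 * np.pi * (months - 12) / 12.0)
    z = rng.standard_normal(total)
    a = np.zeros(total)
    for t in range(1, total):
        a[t] = p.ar * a[t - 1] + p.innovation_sd * s[t] * z[t]
    a = a[burn:]
    months = months[burn:]
    years = config.start_year + np.arange(12 * config.n_years) // 12
    cyc = seasonal_cycle(config)
    values = cyc[months - 1] + a
    return pd.DataFrame({"year": years, "month": months, "value": values})


def build_geography(config: WorldConfig) -> pd.DataFrame:
    """Pixel table: 0.5° centers, admin/country/region membership, weights.

    Countries are longitude strips; each country's admin units stack in
    latitude blocks of ``pixels_per_admin`` pixels.  Population is log-normal
    per pixel; land area follows the cos(latitude) shrinkage of a 0.5° cell.
    """
    rng = _rng(config, 1)
    rows = []
    pixel = 0
    for c in range(config.n_countries):
        for a in range(config.admin1_per_country):
            for k in range(config.pixels_per_admin):
                lat = -10.0 + 0.5 * (a * config.pixels_per_admin + k)
                lon = 100.0 + 0.5 * c
                rows.append(
                    (
                        pixel,
                        lat,
                        lon,
                        f"C{c:02d}",
                        f"C{c:02d}A{a}",
                        config.region_of(c),
                    )
                )
                pixel += 1
    out = pd.DataFrame(
        rows, columns=["pixel", "lat", "lon", "country", "admin1", "region"]
    )
    out["population"] = rng.lognormal(10.0, 1.0, size=len(out))
    out["land_area"] = 3081.0 * np.cos(np.deg2rad(out["lat"].to_numpy()))
    return out


def _planted_loadings(config: WorldConfig, pixels: pd.DataFrame):
    """Per-pixel planted temperature and (signed) precipitation loadings."""
    tele = config.tele
    n_tele = config.n_countries - tele.n_zero_countries
    if n_tele < 1:
        raise ValueError("at least one teleconnected country is required")
    c_idx = pixels["country"].str.slice(1).astype(int).to_numpy()
    a_idx = pixels["admin1"].str.split("A").str[-1].astype(int).to_numpy()
    is_tele = c_idx < n_tele
    n_pos = max(1, round(tele.pos_admin_fraction * config.admin1_per_country))
    pos_admin = a_idx < n_pos
    temp_load = np.where(is_tele, tele.temp_loading, 0.0)
    precip_load = np.where(
        is_tele, np.where(pos_admin, tele.precip_loading, -tele.precip_loading), 0.0
    )
    return temp_load, precip_load, is_tele, pos_admin & is_tele


def simulate_climate_grid(nino: pd.DataFrame, config: WorldConfig) -> ClimateGrid:
    """Gridded monthly fields driven by the lag-2 index anomaly.

    pixel temperature(t) = climatology(month, lat) + loading·anom(t−2) + noise,
    precipitation analogous with a signed loading and a floor at zero.  The
    grid's time axis starts two months after the index so every grid month
    has a defined lag-2 index value.
    """
    nino = expo.validate_nino(nino)
    first = (config.start_year, 1)
    last = (config.start_year + config.n_years - 1, 12)
    have = set(zip(nino["year"], nino["month"]))
    if first not in have or last not in have:
        raise ValueError("index series does not cover the simulation window")

    pixels = build_geography(config)
    temp_load, precip_load, _, _ = _planted_loadings(config, pixels)

    cyc = seasonal_cycle(config)
    anom = nino["value"].to_numpy() - cyc[nino["month"].to_numpy() - 1]
    lag = 2
    # grid months lag..end of the index window
    years = nino["year"].to_numpy()[lag:]
    months = nino["month"].to_numpy()[lag:]
    lag_anom = anom[:-lag]
    T = len(years)
    n = len(pixels)

    rng = _rng(config, 2)
    lat = pixels["lat"].to_numpy()
    t_clim = (
        25.0
        - 0.3 * np.abs(lat)[:, None]
        + 3.0 * np.cos(2 * np.pi * (months[None, :] - 7) / 12.0)
    )
    tele = config.tele
    temp = (
        t_clim
        + temp_load[:, None] * lag_anom[None, :]
        + tele.temp_noise_sd * rng.standard_normal((n, T))
    )
    p_clim = tele.precip_climatology * (
        1.0 + 0.5 * np.cos(2 * np.pi * (months[None, :] - 8) / 12.0)
    ) * np.ones((n, 1))
    precip = (
        p_clim
        + precip_load[:, None] * lag_anom[None, :]
        + tele.precip_noise_sd * rng.standard_normal((n, T))
    )
    precip = np.maximum(precip, 0.0)
    return ClimateGrid(
        pixels=pixels, years=years, months=months, temperature=temp, precipitation=precip
    )


def ground_truth_teleconnection(config: WorldConfig) -> TeleconnectionMap:
    """Oracle teleconnection map implied by the planted loadings (no data)."""
    pixels = build_geography(config)
    _, _, is_tele, pos_pixel = _planted_loadings(config, pixels)
    table = pixels[["pixel", "country", "admin1", "population", "land_area"]].copy()
    table["temp_sig_months"] = np.where(is_tele, 12, 0)
    table["temp_teleconnected"] = is_tele
    table["precip_pos_sig_months"] = np.where(pos_pixel, 12, 0)
    table["precip_pos_flag"] = pos_pixel
    table["precip_neg_sig_months"] = np.where(is_tele & ~pos_pixel, 12, 0)
    country_flags = (
        table.groupby("country")["temp_teleconnected"].agg(lambda s: bool(s.all())).sort_index()
    )
    admin_flags = (
        table.groupby("admin1")["precip_pos_flag"].agg(lambda s: bool(s.all())).sort_index()
    )
    return TeleconnectionMap(
        pixel_table=table,
        country_flags=country_flags,
        admin_pos_precip=admin_flags,
        params={"source": "ground_truth"},
    )


def planted_parameters(config: WorldConfig) -> dict:
    """Deterministic draw of the nuisance parameters of the outcome model.

    Region trend slopes, region×month effects, and country×urban intercepts
    are drawn once from a dedicated stream, so they are identical however
    many children are simulated.
    """
    rng = _rng(config, 3)
    e = config.effects
    regions = [f"R{r}" for r in range(config.n_regions)]
    region_trends = dict(
        zip(regions, e.region_trend_sd * rng.standard_normal(config.n_regions))
    )
    month_effects = {
        r: (e.month_effect_sd * rng.standard_normal(12)).tolist() for r in regions
    }
    cells = {}
    for c in range(config.n_countries):
        for u in (0, 1):
            cells[f"C{c:02d}|{u}"] = float(
                e.alpha + e.cell_intercept_sd * rng.standard_normal()
            )
    return {
        "region_trends": region_trends,
        "month_effects": month_effects,
        "cell_intercepts": cells,
    }


def simulate_surveys(
    nino: pd.DataFrame,
    tele: TeleconnectionMap,
    config: WorldConfig,
    n_children: int | None = None,
) -> pd.DataFrame:
    """Child-level survey microdata following the planted panel model.

    Survey waves rotate round-robin over countries (one wave every
    ``survey_interval`` years per country, starting the second calendar year
    so that January–April interviews always map to an available tropical
    year).  Outcomes follow

        Y = cell_intercept(country, urban) + β·NINO_t [+ (β_p−β_n)·NINO_t·pos]
            + γ_edu·edu + γ_age·age + trend_region·(year − start)
            + month_effect(region, month) [+ year/admin shocks] + noise,

    with NINO_t the May–December mean of the child's assigned tropical year
    and `pos` the admin1 positive-precipitation flag from ``tele``.  A
    configurable fraction of anthropometric values is quality-flagged (set
    to improbable magnitudes) and another fraction set missing.
    """
    nino = expo.validate_nino(nino)
    sp = config.survey
    n_children = int(sp.n_children if n_children is None else n_children)
    means = expo.tropical_year_means(nino)
    exposure_by_year = means.to_dict()

    wave_years = range(config.start_year + 1, config.start_year + config.n_years)
    waves = []
    for y in wave_years:
        for c in range(config.n_countries):
            if (y - config.start_year - 1 - c) % sp.survey_interval == 0:
                waves.append((c, y))
    if not waves:
        raise ValueError("no survey waves in the configured window")
    for _, y in waves:
        if y not in exposure_by_year or (y - 1) not in exposure_by_year:
            raise ValueError(f"survey year {y} outside the index window")

    nuis = planted_parameters(config)
    admin_pos = tele.admin_pos_precip.to_dict()
    e = config.effects
    n_tele = config.n_countries - config.tele.n_zero_countries

    rng = _rng(config, 4)
    shock_rng = _rng(config, 5)
    years_all = sorted({y for y in exposure_by_year})
    admins_all = [a for c in range(config.n_countries) for a in config.admin_ids(c)]
    year_shocks = {
        o: dict(zip(years_all, e.year_shock_sd * shock_rng.standard_normal(len(years_all))))
        for o in OUTCOMES
    }
    admin_shocks = {
        o: dict(zip(admins_all, e.admin_shock_sd * shock_rng.standard_normal(len(admins_all))))
        for o in OUTCOMES
    }

    base = n_children // len(waves)
    extra = n_children - base * len(waves)
    frames = []
    for w, (c, y) in enumerate(waves):
        m = base + (1 if w < extra else 0)
        if m == 0:
            continue
        country = f"C{c:02d}"
        region = config.region_of(c)
        if sp.timing_depends_on_enso:
            x_now = exposure_by_year[y]
            logits = 0.2 * x_now * (np.arange(1, 13) - 6.5) / 6.0
            pm = np.exp(logits) / np.exp(logits).sum()
            months = rng.choice(np.arange(1, 13), size=m, p=pm)
        else:
            months = rng.integers(1, 13, size=m)
        admin_idx = rng.integers(0, config.admin1_per_country, size=m)
        admins = np.array(config.admin_ids(c))[admin_idx]
        cluster_idx = rng.integers(0, sp.clusters_per_wave, size=m)
        cluster_w = rng.lognormal(0.0, sp.weight_sigma, size=sp.clusters_per_wave)
        urban = (rng.random(m) < sp.urban_share).astype(int)
        edu = np.clip(np.round(rng.normal(6.0, 3.0, size=m)), 0, 18)
        age = np.clip(rng.normal(26.0, 6.0, size=m), 15.0, 49.0)
        child_age = rng.integers(0, 60, size=m)
        sex = rng.integers(0, 2, size=m)

        trop = np.where(months >= 5, y, y - 1)
        x = np.array([exposure_by_year[t] for t in trop])
        pos = np.array([bool(admin_pos.get(a, False)) for a in admins])
        is_tele = float(c < n_tele) if e.tele_only else 1.0

        frame = pd.DataFrame(
            {
                "country": country,
                "admin1": admins,
                "region": region,
                "survey": f"{country}-{y}",
                "cluster": [f"{country}-{y}-K{k:03d}" for k in cluster_idx],
                "int_year": y,
                "int_month": months,
                "child_age_months": child_age,
                "sex": sex,
                "urban": urban,
                "mother_edu": edu,
                "mother_age": age,
                "dhs_weight": cluster_w[cluster_idx],
            }
        )
        cell_key = [f"{country}|{u}" for u in urban]
        systematic_common = (
            np.array([nuis["cell_intercepts"][k] for k in cell_key])
            + e.gamma_edu * edu
            + e.gamma_age * age
            + nuis["region_trends"][region] * (y - config.start_year)
            + np.array(nuis["month_effects"][region])[months - 1]
        )
        for o in OUTCOMES:
            bn, bp = e.outcome_betas[o]
            effect = is_tele * (bn * x + (bp - bn) * x * pos)
            yshock = np.array([year_shocks[o][t] for t in trop])
            ashock = np.array([admin_shocks[o][a] for a in admins])
            frame[o] = (
                systematic_common
                + effect
                + yshock
                + ashock
                + e.child_noise_sd * rng.standard_normal(m)
            )
        frames.append(frame)

    out = pd.concat(frames, ignore_index=True)

    # quality flags: improbable magnitudes; missingness: NaN
    nn = len(out)
    for o in OUTCOMES:
        flagged = rng.random(nn) < sp.flagged_fraction
        out[f"{o}_flagged"] = flagged.astype(int)
        out.loc[flagged, o] = np.sign(rng.standard_normal(flagged.sum())) * rng.uniform(
            7.0, 10.0, flagged.sum()
        )
        missing = (rng.random(nn) < sp.missing_fraction) & ~flagged
        out.loc[missing, o] = np.nan
    miss_mother = rng.random(nn) < sp.missing_mother_fraction
    out.loc[miss_mother, ["mother_edu", "mother_age"]] = np.nan
    return out


@dataclass
class World:
    """Bundle of all simulated inputs plus the planted truth."""

    config: WorldConfig
    nino: pd.DataFrame
    grid: ClimateGrid
    tele_truth: TeleconnectionMap
    children: pd.DataFrame
    truth: dict


def simulate_world(
    config: WorldConfig,
    with_grid: bool = True,
    n_children: int | None = None,
) -> World:
    """Generate every input stream from one seeded configuration.

    ``with_grid=False`` skips the gridded fields (survey simulation uses the
    planted teleconnection oracle either way).
    """
    nino = simulate_nino(config)
    grid = simulate_climate_grid(nino, config) if with_grid else None
    tele_truth = ground_truth_teleconnection(config)
    children = simulate_surveys(nino, tele_truth, config, n_children=n_children)
    truth = ground_truth_dict(config)
    return World(config, nino, grid, tele_truth, children, truth)


def ground_truth_dict(config: WorldConfig) -> dict:
    """All planted parameters, for sidecar files and test harnesses."""
    tele = ground_truth_teleconnection(config)
    return {
        "config": asdict(config),
        "nuisance": planted_parameters(config),
        "teleconnected_countries": tele.teleconnected_countries(),
        "positive_precip_admins": sorted(
            tele.admin_pos_precip.index[tele.admin_pos_precip].tolist()
        ),
    }


def write_ground_truth(config: WorldConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(ground_truth_dict(config), fh, indent=2, default=float)


def config_with(config: WorldConfig, **kwargs) -> WorldConfig:
    """Shallow-update helper (`dataclasses.replace` passthrough)."""
    return replace(config, **kwargs)
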