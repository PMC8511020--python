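"""Survey microdata preparation: filtering, thresholds, exposure, weights.

Child anthropometric z-scores (WAZ, WHZ, BMI-z) arrive pre-computed against
an international growth reference.  Preparation consists of

1. removing quality-flagged (improbable) and missing values of the outcome
   under analysis, with an auditable removal log;
2. constructing WHO threshold indicators — *underweight* is WAZ strictly
   below −2σ, *wasted* is WHZ strictly below −2σ;
3. attaching the tropical-year ENSO exposure and the admin-level
   positive-precipitation teleconnection flag to each interview date;
4. building observation weights for the two estimands: the effect on the
   *average country* (survey weights normalized to sum to one within each
   country, pooling its surveys) or on the *average child* (those weights
   multiplied by the country's under-5 population).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import assign_tropical_year
from .teleconnection import TeleconnectionMap

__all__ = [
    "RemovalLog",
    "filter_anthropometrics",
    "threshold_indicators",
    "attach_exposure",
    "apply_admin_aliases",
    "drop_missing_mother",
    "build_weights",
]


@dataclass
class RemovalLog:
    """Counts of records removed, by reason."""

    outcome: str
    n_input: int
    n_flagged: int
    n_missing: int

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_flagged - self.n_missing

    @property
    def flagged_fraction(self) -> float:
        return self.n_flagged / self.n_input if self.n_input else 0.0

    @property
    def missing_fraction(self) -> float:
        return self.n_missing / self.n_input if self.n_input else 0.0

    def __str__(self) -> str:
        return (
            f"{self.outcome}: {self.n_input} records in; removed "
            f"{self.n_flagged} flagged ({100 * self.flagged_fraction:.2f}%) and "
            f"{self.n_missing} missing ({100 * self.missing_fraction:.2f}%); "
            f"{self.n_kept} kept"
        )


def filter_anthropometrics(raw: pd.DataFrame, outcome: str):
    """Drop records flagged as improbable or missing on ``outcome``.

    Expects columns ``{outcome}`` and ``{outcome}_flagged``.  Returns
    ``(filtered, RemovalLog)``; raises if nothing survives.
    """
    flag_col = f"{outcome}_flagged"
    for col in (outcome, flag_col):
        if col not in raw.columns:
            raise ValueError(f"missing required column {col!r}")
    flagged = raw[flag_col].astype(bool)
    missing = raw[outcome].isna() & ~flagged
    keep = ~(flagged | missing)
    log = RemovalLog(
        outcome=outcome,
        n_input=len(raw),
        n_flagged=int(flagged.sum()),
        n_missing=int(missing.sum()),
    )
    out = raw.loc[keep].copy()
    if out.empty:
        raise ValueError(f"all records removed while filtering {outcome!r}")
    return out, log


def threshold_indicators(table: pd.DataFrame) -> pd.DataFrame:
    """Add WHO threshold indicators (strict inequalities at −2σ).

    ``underweight = 1(WAZ < −2)``; ``wasted = 1(WHZ < −2)``.  A z-score of
    exactly −2.0 is *not* below the threshold.  Missing z-scores yield
    missing indicators.
    """
    out = table.copy()
    if "waz" in out.columns:
        out["underweight"] = (out["waz"] < -2.0).astype(float).where(out["waz"].notna())
    if "whz" in out.columns:
        out["wasted"] = (out["whz"] < -2.0).astype(float).where(out["whz"].notna())
    return out


def apply_admin_aliases(table: pd.DataFrame, aliases: pd.DataFrame) -> pd.DataFrame:
    """Standardize admin1 labels via an alias table (columns old, new).

    Border changes between survey rounds are handled by mapping obsolete
    unit labels onto their superset before any grouping.
    """
    mapping = dict(zip(aliases["old"], aliases["new"]))
    out = table.copy()
    out["admin1"] = out["admin1"].map(lambda a: mapping.get(a, a))
    return out


def attach_exposure(
    table: pd.DataFrame,
    exposure_table: pd.DataFrame,
    tele: TeleconnectionMap | None = None,
) -> pd.DataFrame:
    """Attach tropical year, NINO exposure, and the positive-precip flag.

    The tropical year follows the May boundary of the interview date; the
    exposure is that year's May–December index mean from ``exposure_table``.
    With a teleconnection map supplied, rows also get ``pos_precip`` (admin1
    flag) and rows' countries can be restricted later via
    ``tele.teleconnected_countries()``.
    """
    out = table.copy()
    out["tropical_year"] = assign_tropical_year(
        out["int_year"].to_numpy(), out["int_month"].to_numpy()
    )
    exp_map = dict(
        zip(exposure_table["tropical_year"], exposure_table["mean_may_dec"])
    )
    missing_years = sorted(set(out["tropical_year"]) - set(exp_map))
    if missing_years:
        raise ValueError(f"no exposure for tropical years {missing_years}")
    out["nino"] = out["tropical_year"].map(exp_map)
    if tele is not None:
        admin_pos = tele.admin_pos_precip.to_dict()
        unknown = sorted(set(out["admin1"]) - set(admin_pos))
        if unknown:
            raise ValueError(f"admin units missing from teleconnection map: {unknown}")
        out["pos_precip"] = out["admin1"].map(admin_pos).astype(bool)
    return out


@dataclass
class MotherCovariateLog:
    n_input: int
    n_dropped: int
    imputed: bool = False
    imputed_countries: list = field(default_factory=list)


def drop_missing_mother(table: pd.DataFrame, impute: bool = False):
    """Handle missing mother's education/age: drop (default) or impute.

    Imputation substitutes country means, recorded in the log.
    """
    cols = ["mother_edu", "mother_age"]
    missing = table[cols].isna().any(axis=1)
    if impute:
        out = table.copy()
        for col in cols:
            means = out.groupby("country")[col].transform("mean")
            out[col] = out[col].fillna(means)
        log = MotherCovariateLog(
            n_input=len(table),
            n_dropped=0,
            imputed=True,
            imputed_countries=sorted(table.loc[missing, "country"].unique().tolist()),
        )
        return out, log
    out = table.loc[~missing].copy()
    return out, MotherCovariateLog(n_input=len(table), n_dropped=int(missing.sum()))


def build_weights(
    table: pd.DataFrame,
    mode: str = "average_country",
    populations: dict | pd.Series | None = None,
    per_survey: bool = False,
) -> pd.DataFrame:
    """Construct the observation-weight column ``w``.

    ``average_country``: sampling weights normalized so all observations of a
    country — pooling its surveys — sum to exactly one; each country then
    contributes equally (the estimand is the effect in the average sample
    country).  With ``per_survey=True`` each survey is first normalized to
    1/(number of surveys in its country), which still gives unit country
    totals but equalizes surveys within country.

    ``average_child``: the normalized weights are multiplied by the country's
    under-5 population, so a country's weight mass is proportional to its
    child population (the estimand is the effect on the average child).
    """
    if mode not in ("average_country", "average_child"):
        raise ValueError("mode must be 'average_country' or 'average_child'")
    if (table["dhs_weight"] <= 0).any():
        raise ValueError("dhs_weight must be strictly positive")
    out = table.copy()
    if per_survey:
        survey_tot = out.groupby("survey")["dhs_weight"].transform("sum")
        n_surveys = out.groupby("country")["survey"].transform("nunique")
        out["w"] = out["dhs_weight"] / survey_tot / n_surveys
    else:
        country_tot = out.groupby("country")["dhs_weight"].transform("sum")
        out["w"] = out["dhs_weight"] / country_tot
    if mode == "average_child":
        if populations is None:
            raise ValueError("average_child mode requires country populations")
        pop = pd.Series(populations)
        missing = sorted(set(out["country"]) - set(pop.index))
        if missing:
            raise ValueError(f"missing under-5 population for countries: {missing}")
        out["w"] = out["w"] * out["country"].map(pop)
    return out
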