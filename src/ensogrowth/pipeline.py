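"""End-to-end assembly: from raw inputs to the estimation-ready child table.

The canonical sequence: build the exposure table from the index, filter the
microdata on the requested outcome, resolve mother covariates, add WHO
threshold indicators, attach tropical-year exposure and the admin-level
positive-precipitation flag, restrict to teleconnected countries, and build
the observation weights.
"""

from __future__ import annotations

import pandas as pd

from .exposure import build_exposure_table
from .surveys import (
    attach_exposure,
    build_weights,
    drop_missing_mother,
    filter_anthropometrics,
    threshold_indicators,
)
from .teleconnection import TeleconnectionMap

__all__ = ["prepare_estimation_table"]


def prepare_estimation_table(
    nino: pd.DataFrame,
    tele: TeleconnectionMap,
    children: pd.DataFrame,
    outcome: str = "waz",
    weight_mode: str = "average_country",
    populations=None,
    climatology=None,
    impute_mother: bool = False,
):
    """Prepare the estimation sample for one outcome and weighting scheme.

    Returns ``(table, logs)`` where logs collects the removal and mother-
    covariate records.  The table carries ``nino``, ``tropical_year``,
    ``pos_precip``, threshold indicators and the weight column ``w``, and is
    restricted to temperature-teleconnected countries.
    """
    exposure_table = build_exposure_table(nino, climatology=climatology)
    table, removal_log = filter_anthropometrics(children, outcome)
    table, mother_log = drop_missing_mother(table, impute=impute_mother)
    table = threshold_indicators(table)
    table = attach_exposure(table, exposure_table, tele)
    countries = tele.teleconnected_countries()
    table = table[table["country"].isin(countries)].copy()
    if table.empty:
        raise ValueError("no observations in teleconnected countries")
    table = build_weights(table, weight_mode, populations=populations)
    logs = {"removal": removal_log, "mother": mother_log, "countries": countries}
    return table, logs
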