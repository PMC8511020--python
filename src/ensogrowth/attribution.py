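"""Counterfactual attribution arithmetic for ENSO events.

Translates a per-°C regression coefficient and an event-year index anomaly
into population-scale statements: the mean z-score (or probability) shift,
the count of children pushed across a threshold, the number of children a
given nutrition intervention would have to reach to offset the event, and
the annual pace of prevalence decline a target year implies.

All operations are linear in anomaly, coefficient and population.  Reported
headline numbers follow the two-significant-figure convention, and — as in
the published chains these calculations mirror — rounding happens at each
reporting boundary (e.g. a probability shift is rounded to 1.9 percentage
points *before* scaling by the under-5 population); full-precision values
are always returned alongside.

Intervention effect sizes (per-child WAZ gains with confidence intervals)
are external published inputs supplied via a YAML config, never hard-coded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import yaml

__all__ = [
    "EventScenario",
    "InterventionSpec",
    "event_effect",
    "affected_children",
    "intervention_equivalence",
    "sdg_pace",
    "round_sig",
    "load_interventions",
    "load_scenario",
    "attribution_report",
]


def round_sig(x: float, digits: int = 2) -> float:
    """Round to ``digits`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass
class EventScenario:
    """An ENSO event translated into exposure terms.

    ``anomaly``: detrended event-year May–December index anomaly (°C);
    ``coefficient``: estimated effect per °C (σ-units for z-score outcomes,
    probability for threshold outcomes); ``population``: children under 5 in
    the affected sample; ``baseline_prevalence``: pre-event prevalence of the
    threshold outcome (fraction), where relevant.
    """

    anomaly: float
    coefficient: float
    population: float = 0.0
    baseline_prevalence: float | None = None

    def __post_init__(self):
        if self.population < 0:
            raise ValueError("population must be non-negative")
        if self.baseline_prevalence is not None and not (
            0.0 <= self.baseline_prevalence <= 1.0
        ):
            raise ValueError("baseline prevalence must lie in [0, 1]")


@dataclass
class InterventionSpec:
    """A nutrition intervention's published per-child WAZ effect (σ-units)."""

    name: str
    effect_size: float
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self):
        if self.effect_size <= 0:
            raise ValueError("intervention effect size must be positive")


def event_effect(anomaly: float, coefficient: float) -> float:
    """Per-child shift caused by the event: ``anomaly × coefficient`` (signed).

    A negative σ-coefficient with a positive (El Niño) anomaly yields a
    negative WAZ shift; a La Niña (negative) anomaly reverses the sign.
    """
    return anomaly * coefficient


def affected_children(shift: float, population: float) -> float:
    """Children moved across a threshold: ``shift × population``.

    ``shift`` is a probability change (|shift| ≤ 1); the sign carries
    through (negative = children lifted out).
    """
    if abs(shift) > 1:
        raise ValueError("a probability shift cannot exceed 1 in magnitude")
    return shift * population


def intervention_equivalence(
    total_deficit: float, interventions: list[InterventionSpec]
) -> list[dict]:
    """Children each intervention must reach to offset a total σ-deficit.

    ``total_deficit`` is the event's WAZ effect summed over all children
    (|per-child shift| × population, in child-σ units).  Per intervention,
    required children = deficit / per-child effect size; the CI follows by
    dividing by the effect-size CI bounds (order reverses: a larger effect
    needs fewer children).
    """
    if total_deficit < 0:
        raise ValueError("total deficit must be non-negative (use |shift|·pop)")
    rows = []
    for iv in interventions:
        row = {
            "name": iv.name,
            "children": total_deficit / iv.effect_size,
            "children_ci_low": (
                total_deficit / iv.ci_high if iv.ci_high else None
            ),
            "children_ci_high": (
                total_deficit / iv.ci_low if iv.ci_low else None
            ),
        }
        rows.append(row)
    return rows


def sdg_pace(
    prevalence: float, base_year: int, target_year: int = 2030
) -> float:
    """Percentage points per year needed to reach zero by the target year.

    ``100 × prevalence / (target_year − base_year)``.
    """
    if target_year <= base_year:
        raise ValueError("target year must lie after the base year")
    if not (0.0 <= prevalence <= 1.0):
        raise ValueError("prevalence must lie in [0, 1]")
    return 100.0 * prevalence / (target_year - base_year)


def load_interventions(path) -> list[InterventionSpec]:
    """Read intervention effect sizes from a YAML config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [
        InterventionSpec(
            name=item["name"],
            effect_size=float(item["effect_size_sigma"]),
            ci_low=float(item["ci_low"]) if "ci_low" in item else None,
            ci_high=float(item["ci_high"]) if "ci_high" in item else None,
        )
        for item in raw["interventions"]
    ]


def load_scenario(path) -> dict:
    """Read an event scenario config (anomaly, coefficients, population)."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def attribution_report(scenario: dict, interventions: list[InterventionSpec]) -> dict:
    """Full attribution chain for an event scenario.

    Expects scenario keys ``anomaly_c``, ``waz_coefficient_per_c`` (signed,
    σ/°C), ``underweight_coefficient_per_c`` (probability/°C),
    ``under5_population``, ``underweight_prevalence``, ``sdg_base_year``,
    ``sdg_target_year``.  Returns raw and reporting-rounded values; the
    rounded chain reproduces published-style arithmetic (round the
    probability shift to two significant figures before scaling by
    population; round the σ-shift before building the intervention deficit).
    """
    anomaly = float(scenario["anomaly_c"])
    waz_shift = event_effect(anomaly, float(scenario["waz_coefficient_per_c"]))
    prob_shift = event_effect(
        anomaly, float(scenario["underweight_coefficient_per_c"])
    )
    pop = float(scenario["under5_population"])
    prob_shift_rounded = round_sig(prob_shift, 2)
    n_underweight = affected_children(prob_shift_rounded, pop)
    deficit = abs(round_sig(waz_shift, 2)) * pop
    equivalence = intervention_equivalence(deficit, interventions)
    pace = sdg_pace(
        float(scenario["underweight_prevalence"]),
        int(scenario["sdg_base_year"]),
        int(scenario.get("sdg_target_year", 2030)),
    )
    return {
        "anomaly_c": anomaly,
        "waz_shift_sigma": waz_shift,
        "waz_shift_sigma_reported": round_sig(waz_shift, 2),
        "underweight_shift": prob_shift,
        "underweight_shift_pp_reported": round_sig(100 * prob_shift, 2),
        "children_underweight": n_underweight,
        "children_underweight_reported": round_sig(n_underweight, 2),
        "total_deficit_child_sigma": deficit,
        "interventions": equivalence,
        "sdg_pace_pp_per_year": pace,
        "sdg_pace_pp_per_year_reported": round_sig(pace, 2),
    }
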