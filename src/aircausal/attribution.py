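"""Attributable annual visits from multi-year pollutant concentration changes.

Given a pollutant whose mean concentration fell from ``conc_start`` to
``conc_end`` over a study period, its per-IQR causal effect on expected
daily visits converts into an attributable annual burden:

    attributable = (Δconcentration / IQR) × per-IQR effect × days_per_year

i.e. the concentration change expressed in IQR units, times the daily-visit
change per IQR, times the days in a year.  Dividing by the observed change
in annual visits between the endpoint years gives each pollutant's share of
the real reduction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AttributionError",
    "UnitMismatchError",
    "AttributionResult",
    "attributable_visits",
    "reduction_share",
    "real_reduction",
    "attribute_pollutant",
    "select_attribution_effect",
]


class AttributionError(ValueError):
    """Invalid attribution input."""


class UnitMismatchError(AttributionError):
    """Concentration unit does not match the unit recorded for the series."""


@dataclass
class AttributionResult:
    pollutant: str
    conc_start: float
    conc_end: float
    delta: float
    iqr: float
    causal_effect_iqr: float
    attributable_visits_per_year: float
    share_of_real_reduction: float | None = None
    unit: str = ""


def attributable_visits(
    conc_start: float,
    conc_end: float,
    iqr: float,
    causal_effect_iqr: float,
    days_per_year: float = 365.0,
) -> float:
    """((conc_start − conc_end) / iqr) × per-IQR effect × days_per_year."""
    if iqr <= 0:
        raise AttributionError("iqr must be strictly positive")
    return (conc_start - conc_end) / iqr * causal_effect_iqr * days_per_year


def reduction_share(attributable: float, real_reduction: float) -> float:
    """Percent of the observed visit reduction explained by one pollutant."""
    if real_reduction == 0:
        raise AttributionError("real_reduction must be nonzero")
    return 100.0 * attributable / real_reduction


def real_reduction(visits_year_a: int, visits_year_b: int) -> int:
    """Observed visit reduction from year a to year b (negative = increase)."""
    if visits_year_a < 0 or visits_year_b < 0:
        raise AttributionError("visit counts must be non-negative")
    return int(visits_year_a) - int(visits_year_b)


def attribute_pollutant(
    pollutant: str,
    conc_start: float,
    conc_end: float,
    iqr: float,
    causal_effect_iqr: float,
    days_per_year: float = 365.0,
    observed_reduction: float | None = None,
    unit: str = "",
    expected_unit: str | None = None,
) -> AttributionResult:
    """Full attribution record for one pollutant, with a unit-coherence guard.

    When ``expected_unit`` (the unit tag recorded on the environmental
    series) is supplied it must equal ``unit``; this guards against feeding a
    μg/m³ concentration change to an effect estimated on a mg/m³ series —
    the classic CO bookkeeping trap.
    """
    if expected_unit is not None and unit != expected_unit:
        raise UnitMismatchError(
            f"{pollutant}: concentration unit {unit!r} does not match the "
            f"series unit {expected_unit!r}"
        )
    attributable = attributable_visits(
        conc_start, conc_end, iqr, causal_effect_iqr, days_per_year
    )
    share = (
        reduction_share(attributable, observed_reduction)
        if observed_reduction is not None
        else None
    )
    return AttributionResult(
        pollutant=pollutant,
        conc_start=conc_start,
        conc_end=conc_end,
        delta=conc_start - conc_end,
        iqr=iqr,
        causal_effect_iqr=causal_effect_iqr,
        attributable_visits_per_year=attributable,
        share_of_real_reduction=share,
        unit=unit,
    )


def select_attribution_effect(
    sweep: pd.DataFrame, treatment: str, alpha: float = 0.05
) -> tuple[int, float]:
    """Which lag's causal effect feeds attribution: the maximum significant
    per-IQR effect across the sweep (the lag at which the pollutant's causal
    influence peaks).  Returns ``(lag, causal_effect)``.
    """
    grp = sweep[(sweep["treatment"] == treatment) & sweep["significant"]]
    grp = grp[np.isfinite(grp["causal_effect"])]
    if grp.empty:
        raise AttributionError(
            f"no significant causal effect for {treatment!r} at any lag"
        )
    best = grp.loc[grp["causal_effect"].idxmax()]
    return int(best["lag"]), float(best["causal_effect"])
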