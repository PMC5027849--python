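"""ICD-9 diagnostic grouping, multi-year averaging, and indirect age standardization.

Hospitalization counts are grouped into four major diagnostic categories by
3-digit ICD-9 root code — respiratory (460–519), circulatory (390–459),
mental disorders (290–319), and total — averaged over the study years, and
indirectly age-standardized: each unit's observed events are compared with
the events expected if the standard population's stratum-specific rates
applied to the unit's age structure.  The observed/expected ratio is the
standardized morbidity ratio (SMR); the adjusted rate is SMR times the
standard crude rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: inclusive 3-digit ICD-9 root ranges for the named major diagnostic categories
ICD9_RANGES: dict[str, tuple[int, int]] = {
    "respiratory": (460, 519),
    "circulatory": (390, 459),
    "mental": (290, 319),
}

CATEGORIES = ("total", "respiratory", "circulatory", "mental")

#: conventional five-year age bands, 0-4 through 85+
DEFAULT_STRATA: tuple[str, ...] = tuple(
    f"{lo:02d}_{lo + 4:02d}" for lo in range(0, 85, 5)
) + ("85_plus",)

EVENT_COLUMNS = ["unit_id", "age_stratum", "category", "year", "count"]


@dataclass(frozen=True)
class StandardPopulation:
    """Stratum-specific event rates (events per person-period) of the reference population."""

    rates: pd.Series  # index: age-stratum labels
    crude_rate: float

    def __post_init__(self) -> None:
        if (self.rates < 0).any() or self.crude_rate < 0:
            raise ValueError("standard population rates must be >= 0")


@dataclass(frozen=True)
class AdjustedRate:
    unit_id: object
    category: str
    observed: float
    expected: float
    smr: float  # observed / expected; NaN when expected == observed == 0
    adjusted_rate: float  # smr * standard crude rate


def classify_icd9(code: str) -> str | None:
    """Map an ICD-9 code string to its major diagnostic category.

    Membership is by inclusive integer comparison of the 3-digit root;
    suffixes after the root (``"493.20"``) are ignored.  V-codes, E-codes
    and unparseable codes return ``None`` (excluded from all categories,
    including total, and logged by the caller).
    """
    root = str(code).strip().split(".")[0]
    if not root.isdigit():
        return None
    value = int(root)
    for name, (lo, hi) in ICD9_RANGES.items():
        if lo <= value <= hi:
            return name
    return None


def categorize_events(events: pd.DataFrame, include_unclassified_in_total: bool = False) -> pd.DataFrame:
    """Expand an ICD-9-coded event table into per-category counts.

    Input columns: unit_id, age_stratum, icd9_code, year, count.  Every
    parseable numeric code contributes to ``total``; codes in a named range
    contribute to that category as well.  V/E and unparseable codes are
    dropped (also from total, unless ``include_unclassified_in_total``).
    """
    required = {"unit_id", "age_stratum", "icd9_code", "year", "count"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    cat = events["icd9_code"].map(classify_icd9)
    numeric = events["icd9_code"].astype(str).str.strip().str.split(".").str[0].str.isdigit()
    n_dropped = int((~numeric).sum())
    if n_dropped and not include_unclassified_in_total:
        logger.warning("%d event rows with V/E or unparseable ICD-9 codes excluded", n_dropped)

    in_total = events if include_unclassified_in_total else events[numeric]
    frames = [in_total.assign(category="total")]
    named = events[cat.notna()].assign(category=cat[cat.notna()])
    frames.append(named)
    out = pd.concat(frames, ignore_index=True)
    return (
        out.groupby(["unit_id", "age_stratum", "category", "year"], as_index=False)["count"]
        .sum()[EVENT_COLUMNS]
    )


def average_years(events: pd.DataFrame, years: list[int] | None = None) -> pd.DataFrame:
    """Arithmetic mean of counts over the listed years, one averaged period out.

    A (unit, stratum, category) absent in some listed year counts as 0 for
    that year (logged).  Output columns: unit_id, age_stratum, category,
    count — fractional means preserved.
    """
    if years is None:
        years = sorted(events["year"].unique())
    if len(years) == 0:
        raise ValueError("average_years requires at least one year")
    sub = events[events["year"].isin(years)]
    grouped = sub.groupby(["unit_id", "age_stratum", "category"], as_index=False)["count"].sum()
    n_years_present = sub.groupby(["unit_id", "age_stratum", "category"])["year"].nunique()
    if (n_years_present < len(years)).any():
        n_incomplete = int((n_years_present < len(years)).sum())
        logger.warning(
            "%d (unit, stratum, category) groups missing one or more of years %s; missing years count as 0",
            n_incomplete, years,
        )
    grouped["count"] = grouped["count"] / len(years)
    return grouped


def indirect_adjust(
    populations: pd.Series,
    observed_by_stratum: pd.Series,
    std: StandardPopulation,
    unit_id=None,
    category: str = "total",
) -> AdjustedRate:
    """Indirect age standardization of one unit against the standard population.

    ``expected = sum_s std.rate(s) * pop(s)``; ``smr = observed / expected``;
    ``adjusted_rate = smr * std.crude_rate``.
    """
    pop = populations.astype(float)
    missing = std.rates.index.difference(pop.index)
    if len(missing):
        raise ValueError(f"unit populations missing strata: {missing.tolist()}")
    obs = float(observed_by_stratum.reindex(pop.index, fill_value=0.0).sum())
    expected = float((std.rates * pop.reindex(std.rates.index)).sum())
    if expected == 0.0:
        if obs > 0:
            raise ValueError(
                f"unit {unit_id!r}: expected events are 0 but {obs} observed"
            )
        smr = float("nan")  # undefined; reported as missing
    else:
        smr = obs / expected
    return AdjustedRate(
        unit_id=unit_id,
        category=category,
        observed=obs,
        expected=expected,
        smr=smr,
        adjusted_rate=smr * std.crude_rate,
    )


def adjusted_rates(
    populations: pd.DataFrame,
    events_avg: pd.DataFrame,
    std_by_category: dict[str, StandardPopulation],
    categories: tuple[str, ...] = CATEGORIES,
) -> pd.DataFrame:
    """Indirectly standardized rates for every unit and category.

    ``populations``: units x strata person counts.  ``events_avg``: averaged
    event table (unit_id, age_stratum, category, count).
    """
    rows = []
    for category in categories:
        std = std_by_category[category]
        ev = events_avg[events_avg["category"] == category]
        obs = ev.pivot_table(index="unit_id", columns="age_stratum", values="count", fill_value=0.0)
        for unit_id in populations.index:
            observed = obs.loc[unit_id] if unit_id in obs.index else pd.Series(0.0, index=populations.columns)
            r = indirect_adjust(populations.loc[unit_id], observed, std, unit_id=unit_id, category=category)
            rows.append(r.__dict__)
    return pd.DataFrame(rows)


def standard_from_region(
    populations: pd.DataFrame,
    events_avg: pd.DataFrame,
    category: str,
) -> StandardPopulation:
    """Region-wide stratum rates and crude rate, usable as a standard population."""
    pop_s = populations.sum(axis=0)
    ev = events_avg[events_avg["category"] == category]
    obs_s = ev.groupby("age_stratum")["count"].sum().reindex(pop_s.index, fill_value=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = (obs_s / pop_s).fillna(0.0)
    total_pop = float(pop_s.sum())
    crude = float(obs_s.sum()) / total_pop if total_pop else 0.0
    return StandardPopulation(rates=rates, crude_rate=crude)
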