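"""Synthetic study regions for exercising the ADI pipeline end to end.

Real inputs of this kind (census extracts, hospitalization registries) are
not redistributable, so the simulator emulates their statistical structure:

* a square region of area units (grid or uniform-random centroids) whose
  latent deprivation ``L(u)`` is a broad linear trend across the extent plus
  small disc-shaped pockets of excess deprivation;
* the 17 census variables generated as monotone transforms of ``L`` (logit
  link for percentages, log link for dollar amounts), each with independent
  Gaussian noise and the correct deprivation direction, so the composite
  score recovers the latent factor;
* age-stratified populations around a mean unit size, and hospitalization
  counts drawn per (unit, age stratum, category) as Binomial(pop, p) with
  ``logit(p) = logit(baseline) + effect_log_or * D(u)``, where ``D(u)`` is
  the deprivation signal on the configured scale — the unit's latent
  deprivation centered on its local window mean (``local``), on the region
  mean (``regional``), or zero (``none``).

The ``local-pockets`` preset is the headline scenario: the true effect acts
on *locally relative* deprivation, so locally calibrated flags should show
the strongest association, degrading with window radius down to the
regional calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .ageadjust import DEFAULT_STRATA, EVENT_COLUMNS, StandardPopulation, standard_from_region
from .calibration import StudyRegion
from .variables import ADI_VARIABLES, CURRENCY, PERCENT, RATIO

logger = logging.getLogger(__name__)


def _default_baseline_rates() -> tuple[float, ...]:
    """Annual all-cause hospitalization probability per five-year age band.

    U-shaped in age: elevated in infancy, low through early adulthood,
    rising steeply at older ages.
    """
    mids = np.array([lo + 2.5 for lo in range(0, 85, 5)] + [90.0])
    rates = 0.03 + 0.27 * (mids / 92.5) ** 3
    rates[0] += 0.05  # infant/early-childhood excess
    return tuple(float(r) for r in rates)


def _default_age_profile() -> tuple[float, ...]:
    """Population share per five-year band, gently declining with age."""
    w = np.linspace(1.0, 0.35, num=len(DEFAULT_STRATA))
    w /= w.sum()
    return tuple(float(x) for x in w)


#: share of total admissions by diagnostic category ("other" completes the total)
CATEGORY_SHARES: dict[str, float] = {
    "respiratory": 0.15,
    "circulatory": 0.25,
    "mental": 0.10,
    "other": 0.50,
}


@dataclass(frozen=True)
class ScenarioConfig:
    """All knobs of one synthetic scenario; fully reproducible given ``seed``."""

    n_units: int = 400
    layout: str = "uniform_random"  # or "grid"
    extent_km: float = 60.0
    n_pockets: int = 8
    pocket_radius_km: float = 3.0
    trend_amplitude: float = 2.0
    pocket_amplitude: float = 1.5
    noise_sd: float = 0.3
    effect_scale: str = "none"  # "none", "regional", or "local"
    effect_radius_km: float = 10.0  # window radius when effect_scale == "local"
    effect_log_or: float = 0.0  # log-odds increment per unit of deprivation signal
    baseline_rates: tuple[float, ...] = field(default_factory=_default_baseline_rates)
    age_profile: tuple[float, ...] = field(default_factory=_default_age_profile)
    mean_unit_pop: int = 1000
    years: tuple[int, ...] = (2000,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise ValueError("n_units must be >= 2")
        if self.layout not in ("grid", "uniform_random"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.effect_scale not in ("none", "regional", "local"):
            raise ValueError(f"unknown effect_scale {self.effect_scale!r}")
        if self.n_pockets and 2 * self.pocket_radius_km > self.extent_km:
            raise ValueError("pocket diameter exceeds region extent")
        if len(self.baseline_rates) != len(DEFAULT_STRATA) or len(self.age_profile) != len(DEFAULT_STRATA):
            raise ValueError(f"baseline_rates and age_profile must have {len(DEFAULT_STRATA)} entries")
        if not all(0 <= p <= 1 for p in self.baseline_rates):
            raise ValueError("baseline_rates must be probabilities in [0, 1]")


#: named scenario presets
PRESETS: dict[str, ScenarioConfig] = {
    "null": ScenarioConfig(n_units=200, extent_km=45.0, n_pockets=4, effect_scale="none"),
    "regional-effect": ScenarioConfig(
        n_units=200, extent_km=45.0, n_pockets=4, effect_scale="regional", effect_log_or=0.7
    ),
    "local-pockets": ScenarioConfig(
        n_units=400, extent_km=60.0, n_pockets=8,
        effect_scale="local", effect_radius_km=10.0, effect_log_or=0.7,
    ),
}


def preset(name: str, **overrides) -> ScenarioConfig:
    """A named preset, optionally with field overrides (e.g. ``seed=7``)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)


# per-variable link parameters: baseline level and sensitivity to the latent factor
_PERCENT_BASE = {
    "pct_edu_lt9y": 8.0, "pct_edu_hs_plus": 80.0, "pct_white_collar": 55.0,
    "pct_families_poverty": 10.0, "pct_below_150_poverty": 18.0, "pct_unemployed": 6.0,
    "pct_owner_occupied": 65.0, "pct_no_plumbing": 1.0, "pct_single_parent": 12.0,
    "pct_no_vehicle": 10.0, "pct_no_telephone": 3.0, "pct_crowding": 4.0,
}
_CURRENCY_BASE = {
    "median_family_income": 55_000.0, "median_home_value": 180_000.0,
    "median_gross_rent": 750.0, "median_mortgage": 1_300.0,
}
_RATIO_BASE = {"income_disparity": 1.0}
_PERCENT_SLOPE = 0.5
_LOG_SLOPE = 0.25


def generate_region(config: ScenarioConfig) -> StudyRegion:
    """Synthesize a study region (centroids, latent deprivation, census profiles, populations)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_units
    extent_m = config.extent_km * 1000.0

    if config.layout == "grid":
        side = int(np.ceil(np.sqrt(n)))
        step = extent_m / side
        gx, gy = np.meshgrid(np.arange(side), np.arange(side))
        xy = np.column_stack([gx.ravel(), gy.ravel()])[:n] * step + step / 2
        x, y = xy[:, 0].astype(float), xy[:, 1].astype(float)
    else:
        x = rng.uniform(0, extent_m, n)
        y = rng.uniform(0, extent_m, n)

    # latent deprivation: linear west-east trend plus disc pockets
    latent = config.trend_amplitude * (2 * x / extent_m - 1.0)
    pocket_r_m = config.pocket_radius_km * 1000.0
    for _ in range(config.n_pockets):
        cx = rng.uniform(pocket_r_m, extent_m - pocket_r_m)
        cy = rng.uniform(pocket_r_m, extent_m - pocket_r_m)
        inside = np.hypot(x - cx, y - cy) <= pocket_r_m
        latent = latent + config.pocket_amplitude * inside

    cols: dict[str, np.ndarray] = {"x": x, "y": y}
    for name, (_, direction, kind) in ADI_VARIABLES.items():
        signal = direction * latent + rng.normal(0.0, config.noise_sd, n)
        if kind == PERCENT:
            base = _PERCENT_BASE[name]
            cols[name] = 100.0 * expit(logit(base / 100.0) + _PERCENT_SLOPE * signal)
        elif kind == CURRENCY:
            cols[name] = _CURRENCY_BASE[name] * np.exp(_LOG_SLOPE * signal)
        else:
            assert kind == RATIO
            cols[name] = _RATIO_BASE[name] * np.exp(_LOG_SLOPE * signal)

    totals = np.maximum(rng.poisson(config.mean_unit_pop, n), 10 * len(DEFAULT_STRATA))
    shares = np.asarray(config.age_profile, dtype=float)
    shares = shares / shares.sum()
    pops = np.vstack([rng.multinomial(t, shares) for t in totals])
    for j, s in enumerate(DEFAULT_STRATA):
        cols[f"pop_{s}"] = pops[:, j].astype(float)

    ids = pd.Index([f"Z{i:04d}" for i in range(n)], name="unit_id")
    units = pd.DataFrame(cols, index=ids)
    return StudyRegion(
        units=units,
        projected=True,
        strata=DEFAULT_STRATA,
        crs_note=f"synthetic planar coordinates in meters, {config.extent_km} km square extent",
        latent=pd.Series(latent, index=ids, name="latent"),
    )


def deprivation_signal(region: StudyRegion, config: ScenarioConfig) -> pd.Series:
    """The scale-matched deprivation signal ``D(u)`` driving the event model."""
    latent = region.latent
    if latent is None:
        raise ValueError("region carries no latent deprivation (not simulator-generated)")
    if config.effect_scale == "none":
        return pd.Series(0.0, index=region.unit_ids)
    if config.effect_scale == "regional":
        return latent - latent.mean()
    from .calibration import pairwise_distance

    d = pairwise_distance(region).to_numpy()
    within = d <= config.effect_radius_km
    vals = latent.to_numpy()
    window_mean = (within @ vals) / within.sum(axis=1)
    return pd.Series(vals - window_mean, index=region.unit_ids)


def generate_events(
    region: StudyRegion, config: ScenarioConfig
) -> tuple[pd.DataFrame, dict[str, StandardPopulation]]:
    """Hospitalization counts per (unit, stratum, category, year) plus standard populations.

    Named-category counts are drawn independently and ``total`` is their sum
    (with an "other" remainder category completing it), so total admissions
    behave like the union of cause-specific admissions.  Standard
    populations are the region-wide stratum rates per category — the
    synthetic analogue of using the encompassing state as the reference.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    dsig = deprivation_signal(region, config).to_numpy()
    pops = region.populations().to_numpy(dtype=float)  # units x strata
    base = np.asarray(config.baseline_rates, dtype=float)

    records = []
    n_clamped = 0
    totals_by_year: dict[int, np.ndarray] = {}
    for year in config.years:
        total_counts = np.zeros_like(pops)
        for cat, share in CATEGORY_SHARES.items():
            eta = logit(np.clip(base * share, 1e-12, 1 - 1e-12))[None, :] + config.effect_log_or * dsig[:, None]
            p = expit(eta)
            clip = (p <= 0) | (p >= 1)
            if clip.any():
                n_clamped += int(clip.sum())
            p = np.clip(p, 1e-12, 1 - 1e-12)
            counts = rng.binomial(pops.astype(np.int64), p)
            total_counts += counts
            if cat != "other":
                records.append((year, cat, counts))
        records.append((year, "total", total_counts))
        totals_by_year[year] = total_counts
    if n_clamped:
        logger.warning("generate_events: %d event probabilities clamped into (0, 1)", n_clamped)

    frames = []
    strata = list(DEFAULT_STRATA)
    for year, cat, counts in records:
        df = pd.DataFrame(counts, index=region.unit_ids, columns=strata)
        long = df.stack().rename("count").reset_index()
        long.columns = ["unit_id", "age_stratum", "count"]
        long["category"] = cat
        long["year"] = year
        frames.append(long[EVENT_COLUMNS])
    events = pd.concat(frames, ignore_index=True)

    from .ageadjust import average_years

    averaged = average_years(events, list(config.years))
    populations = region.populations()
    std = {
        cat: standard_from_region(populations, averaged, cat)
        for cat in ("total", "respiratory", "circulatory", "mental")
    }
    return events, std
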