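"""Regional and moving-window (local) calibration of ADI percentiles.

Regional calibration ranks every unit against the whole study region.
Local calibration ranks each unit only against the units whose centroids lie
within a fixed radius (10, 20 or 30 km by default), sliding a moving window
across the study area so that "deprived" means deprived relative to the
local context.  A unit in the top 15% of its window is flagged as locally
deprived even when it sits below the regional threshold — the phenomenon the
local calibration exists to expose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adi import DEFAULT_THRESHOLD_PCT, dichotomize, percentile_rank
from .variables import VARIABLE_NAMES

logger = logging.getLogger(__name__)

#: authalic sphere radius used for great-circle distances, km
EARTH_RADIUS_KM = 6371.0088

DEFAULT_RADII_KM = (10.0, 20.0, 30.0)
DEFAULT_MIN_WINDOW = 10

ADI_RESULT_COLUMNS = ["unit_id", "raw_score", "percentile", "flag", "scale", "threshold_pct"]


@dataclass
class StudyRegion:
    """A keyed collection of area units with centroids, populations and profiles.

    ``units`` is indexed by unit_id and holds columns ``x``/``y`` (projected
    meters when ``projected`` else longitude/latitude degrees), one
    ``pop_<stratum>`` column per age stratum, and the 17 census variables.
    """

    units: pd.DataFrame
    projected: bool
    strata: tuple[str, ...]
    crs_note: str = ""
    latent: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.units.index.has_duplicates:
            dupes = self.units.index[self.units.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate unit_id values: {dupes}")
        for col in ("x", "y"):
            if col not in self.units.columns:
                raise ValueError(f"units table lacks centroid column {col!r}")
            if not np.isfinite(self.units[col].astype(float)).all():
                raise ValueError(f"non-finite centroid coordinate in column {col!r}")

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def unit_ids(self) -> pd.Index:
        return self.units.index

    def profiles(self) -> pd.DataFrame:
        return self.units[list(VARIABLE_NAMES)]

    def populations(self) -> pd.DataFrame:
        """Age-stratified populations, one column per stratum label."""
        cols = {f"pop_{s}": s for s in self.strata}
        return self.units[list(cols)].rename(columns=cols)


def pairwise_distance(region: StudyRegion) -> pd.DataFrame:
    """Symmetric centroid-to-centroid distance matrix in km.

    Great-circle (haversine, authalic sphere) for lon/lat regions, Euclidean
    for projected regions whose coordinates are in meters.
    """
    x = region.units["x"].to_numpy(dtype=float)
    y = region.units["y"].to_numpy(dtype=float)
    if region.projected:
        d = np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :]) / 1000.0
    else:
        lon = np.radians(x)
        lat = np.radians(y)
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        d = 2 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=region.unit_ids, columns=region.unit_ids)


def neighborhood(
    region: StudyRegion,
    unit_id,
    radius_km: float,
    distances: pd.DataFrame | None = None,
) -> set:
    """Unit ids whose centroids lie within ``radius_km`` of ``unit_id`` (self included)."""
    if radius_km < 0:
        raise ValueError("radius_km must be >= 0")
    if unit_id not in region.unit_ids:
        raise KeyError(f"unknown unit_id {unit_id!r}")
    if distances is None:
        distances = pairwise_distance(region)
    row = distances.loc[unit_id]
    return set(row.index[row.to_numpy() <= radius_km])


def regional_adi(
    region: StudyRegion,
    raw_scores: pd.Series,
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
) -> pd.DataFrame:
    """ADI results calibrated over the whole study region (scale ``regional``)."""
    scores = _aligned_scores(region, raw_scores)
    if region.n_units < 2:
        raise ValueError("regional calibration requires at least 2 units")
    pct = percentile_rank(scores)
    flag = dichotomize(pct, threshold_pct)
    return pd.DataFrame(
        {
            "unit_id": scores.index,
            "raw_score": scores.to_numpy(),
            "percentile": pct.to_numpy(),
            "flag": pd.array(flag.to_numpy(), dtype="boolean"),
            "scale": "regional",
            "threshold_pct": threshold_pct,
        }
    ).set_index("unit_id", drop=False)


def local_adi(
    region: StudyRegion,
    raw_scores: pd.Series,
    radius_km: float,
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
    min_window: int = DEFAULT_MIN_WINDOW,
    include_self: bool = True,
    distances: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Moving-window ADI: each unit's percentile within its ``radius_km`` neighborhood.

    Windows always contain the central unit when ``include_self`` (the
    default; a percentile of a value within a set is only well defined if
    the value belongs to the set, and inclusion makes the radius-to-infinity
    limit coincide exactly with the regional calibration).  Windows smaller
    than ``min_window`` units yield a percentile but an indeterminate flag
    (``pd.NA``): a top-15% cut among a handful of neighbors is not
    meaningful.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be > 0")
    if not 0 < threshold_pct < 100:
        raise ValueError(f"threshold_pct must be in (0, 100), got {threshold_pct}")
    scores = _aligned_scores(region, raw_scores)
    if distances is None:
        distances = pairwise_distance(region)
    dmat = distances.loc[scores.index, scores.index].to_numpy()
    vals = scores.to_numpy(dtype=float)
    n = len(vals)
    within = dmat <= radius_km
    if include_self:
        np.fill_diagonal(within, True)
    else:
        np.fill_diagonal(within, False)

    pct = np.empty(n)
    flags = np.empty(n, dtype=object)
    cut = 100.0 - threshold_pct
    n_small = 0
    for i in range(n):
        window = vals[within[i]]
        size = window.size
        pct[i] = 100.0 * np.count_nonzero(window <= vals[i]) / size if size else np.nan
        if size < min_window:
            flags[i] = pd.NA
            n_small += 1
        else:
            flags[i] = bool(pct[i] > cut)
    if n_small:
        logger.warning(
            "local_adi radius=%g km: %d of %d windows below min size %d -> indeterminate flag",
            radius_km, n_small, n, min_window,
        )
    return pd.DataFrame(
        {
            "unit_id": scores.index,
            "raw_score": vals,
            "percentile": pct,
            "flag": pd.array(flags, dtype="boolean"),
            "scale": f"local_{radius_km:g}km",
            "threshold_pct": threshold_pct,
        }
    ).set_index("unit_id", drop=False)


def _aligned_scores(region: StudyRegion, raw_scores: pd.Series) -> pd.Series:
    missing = region.unit_ids.difference(raw_scores.index)
    if len(missing):
        raise ValueError(f"raw_scores missing units: {missing.tolist()[:5]}")
    return raw_scores.loc[region.unit_ids].astype(float)
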