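"""Readers, writers, run configuration, and the end-to-end pipeline.

File conventions: UTF-8 comma-separated CSV with a mandatory header row and
"." decimals; GeoJSON per RFC 7946 (lon/lat, WGS84).  Every output CSV
carries a provenance header comment (config hash and package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .adi import DEFAULT_THRESHOLD_PCT, compute_raw_adi
from .ageadjust import (
    CATEGORIES,
    EVENT_COLUMNS,
    StandardPopulation,
    adjusted_rates,
    average_years,
    categorize_events,
)
from .association import compare_scales
from .calibration import (
    DEFAULT_MIN_WINDOW,
    DEFAULT_RADII_KM,
    StudyRegion,
    local_adi,
    pairwise_distance,
    regional_adi,
)
from .variables import VARIABLE_NAMES

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of one end-to-end run; round-trips losslessly through YAML."""

    areas: str = "areas.csv"
    events: str = "events.csv"
    standard: str | None = None  # per-category standard rates CSV; None = derive from region
    out_dir: str = "out"
    radii: list[float] = field(default_factory=lambda: list(DEFAULT_RADII_KM))
    threshold_pct: float = DEFAULT_THRESHOLD_PCT
    categories: list[str] = field(default_factory=lambda: list(CATEGORIES))
    alpha: float = 0.05
    min_window_size: int = DEFAULT_MIN_WINDOW
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")
        if not 0 < self.threshold_pct < 100:
            raise ValueError("threshold_pct must be in (0, 100)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Hash of the analytic configuration (the output location is not analytic)."""
        d = asdict(self)
        d.pop("out_dir")
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


# ---------------------------------------------------------------- readers

def read_areas_csv(path: str | Path) -> StudyRegion:
    """Area-unit table from CSV.

    Required columns: ``unit_id``, centroid (``centroid_lon``/``centroid_lat``
    or projected ``centroid_x``/``centroid_y`` in meters), one
    ``pop_<stratum>`` column per age stratum, and the 17 census variables
    under their canonical snake_case names.
    """
    df = pd.read_csv(path, comment="#")
    return _region_from_frame(df, source=str(path))


def _region_from_frame(df: pd.DataFrame, source: str) -> StudyRegion:
    if "unit_id" not in df.columns:
        raise ValueError(f"{source}: missing column 'unit_id'")
    missing = [v for v in VARIABLE_NAMES if v not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing census variable columns: {missing}")
    lonlat = {"centroid_lon", "centroid_lat"} <= set(df.columns)
    proj = {"centroid_x", "centroid_y"} <= set(df.columns)
    if lonlat and proj:
        raise ValueError(f"{source}: mixed coordinate conventions (both lon/lat and x/y present)")
    if lonlat:
        df = df.rename(columns={"centroid_lon": "x", "centroid_lat": "y"})
        projected = False
    elif proj:
        df = df.rename(columns={"centroid_x": "x", "centroid_y": "y"})
        projected = True
    else:
        raise ValueError(
            f"{source}: centroid columns missing "
            "(need centroid_lon/centroid_lat or centroid_x/centroid_y)"
        )
    pop_cols = [c for c in df.columns if c.startswith("pop_")]
    if not pop_cols:
        raise ValueError(f"{source}: no pop_<stratum> columns found")
    strata = tuple(c[len("pop_"):] for c in pop_cols)
    units = df.set_index("unit_id")
    numeric = ["x", "y", *pop_cols, *VARIABLE_NAMES]
    units[numeric] = units[numeric].astype(float)
    return StudyRegion(units=units, projected=projected, strata=strata, crs_note=source)


def read_areas_geojson(path: str | Path) -> StudyRegion:
    """Area units from a GeoJSON FeatureCollection.

    Each feature's properties must carry ``unit_id``, the population columns
    and the census variables; the centroid is taken from ``centroid_lon``/
    ``centroid_lat`` properties when present, otherwise computed from the
    feature geometry.
    """
    from shapely.geometry import shape

    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    rows = []
    for feat in gj["features"]:
        props = dict(feat.get("properties") or {})
        if "centroid_lon" not in props or "centroid_lat" not in props:
            geom = feat.get("geometry")
            if geom is None:
                raise ValueError(f"{path}: feature without geometry or centroid properties")
            c = shape(geom).centroid
            props["centroid_lon"], props["centroid_lat"] = c.x, c.y
        rows.append(props)
    return _region_from_frame(pd.DataFrame(rows), source=str(path))


def read_events_csv(path: str | Path) -> pd.DataFrame:
    """Event table from CSV: unit_id, age_stratum, icd9_code or category, year, count."""
    df = pd.read_csv(path, comment="#")
    if "icd9_code" in df.columns:
        return categorize_events(df)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: events table missing columns: {sorted(missing)}")
    if (df["count"] < 0).any():
        bad = df.index[df["count"] < 0][0]
        raise ValueError(f"{path}: negative count at row {bad}")
    return df[EVENT_COLUMNS]


def read_standard_csv(path: str | Path) -> dict[str, StandardPopulation]:
    """Standard-population rates from CSV: category, age_stratum, rate, crude_rate."""
    df = pd.read_csv(path, comment="#")
    required = {"category", "age_stratum", "rate", "crude_rate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: standard table missing columns: {sorted(missing)}")
    out = {}
    for cat, sub in df.groupby("category"):
        crude = float(sub["crude_rate"].iloc[0])
        rates = sub.set_index("age_stratum")["rate"].astype(float)
        out[str(cat)] = StandardPopulation(rates=rates, crude_rate=crude)
    return out


# ---------------------------------------------------------------- writers

def _provenance(config_digest: str | None) -> str:
    tag = f" config={config_digest}" if config_digest else ""
    return f"# localadi v{__version__}{tag}\n"


def write_csv(df: pd.DataFrame, path: str | Path, config_digest: str | None = None) -> None:
    """CSV with a provenance comment header; floats at full working precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_provenance(config_digest))
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT)


def write_standard_csv(
    std: dict[str, StandardPopulation], path: str | Path, config_digest: str | None = None
) -> None:
    rows = []
    for cat, sp in std.items():
        for stratum, rate in sp.rates.items():
            rows.append({"category": cat, "age_stratum": stratum, "rate": rate, "crude_rate": sp.crude_rate})
    write_csv(pd.DataFrame(rows), path, config_digest)


def write_areas_csv(region: StudyRegion, path: str | Path, config_digest: str | None = None) -> None:
    df = region.units.reset_index()
    xcol, ycol = ("centroid_x", "centroid_y") if region.projected else ("centroid_lon", "centroid_lat")
    df = df.rename(columns={"x": xcol, "y": ycol})
    write_csv(df, path, config_digest)


def export_geojson(
    region: StudyRegion,
    adi_tables: dict[str, pd.DataFrame],
    path: str | Path,
) -> None:
    """Point FeatureCollection of unit centroids annotated with ADI attributes.

    Each scale's table contributes ``pctile_<scale>`` and ``flag_<scale>``
    properties (flags: true/false/null for indeterminate), suitable for
    choropleth-style rendering in any GIS.
    """
    features = []
    for unit_id, row in region.units.iterrows():
        props: dict = {"unit_id": unit_id}
        for scale, table in adi_tables.items():
            rec = table.loc[unit_id]
            props["adi_raw"] = float(rec["raw_score"])
            props[f"pctile_{scale}"] = float(rec["percentile"])
            flag = rec["flag"]
            props[f"flag_{scale}"] = None if pd.isna(flag) else bool(flag)
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(row["x"]), float(row["y"])]},
                "properties": props,
            }
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# ---------------------------------------------------------------- pipeline

def compute_adi_tables(
    region: StudyRegion,
    radii: list[float],
    threshold_pct: float,
    min_window: int = DEFAULT_MIN_WINDOW,
) -> tuple[pd.Series, dict[str, pd.DataFrame]]:
    """Raw scores plus one calibrated result table per scale (each local radius and regional)."""
    raw = compute_raw_adi(region.profiles())
    distances = pairwise_distance(region)
    tables: dict[str, pd.DataFrame] = {}
    for r in radii:
        tables[f"local_{r:g}km"] = local_adi(
            region, raw, r, threshold_pct, min_window=min_window, distances=distances
        )
    tables["regional"] = regional_adi(region, raw, threshold_pct)
    return raw, tables


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """End-to-end run: ADI at all scales, adjusted rates, OR-by-scale table, GeoJSON.

    Deterministic given inputs and config; outputs land in ``config.out_dir``
    with a provenance header each.  Returns a name -> path map.
    """
    digest = config.digest()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    region = (
        read_areas_geojson(config.areas)
        if str(config.areas).endswith(".geojson") or str(config.areas).endswith(".json")
        else read_areas_csv(config.areas)
    )
    events = read_events_csv(config.events)
    events_avg = average_years(events)
    if config.standard:
        std = read_standard_csv(config.standard)
    else:
        from .ageadjust import standard_from_region

        logger.info("no standard population supplied; deriving region-wide rates")
        std = {c: standard_from_region(region.populations(), events_avg, c) for c in config.categories}

    raw, tables = compute_adi_tables(region, config.radii, config.threshold_pct, config.min_window_size)
    adi_long = pd.concat(tables.values(), ignore_index=True)

    rates = adjusted_rates(region.populations(), events_avg, std, tuple(config.categories))

    or_rows = [
        compare_scales(
            region, raw, events_avg, category=c, radii=tuple(config.radii),
            threshold_pct=config.threshold_pct, min_window=config.min_window_size,
            alpha=config.alpha,
        )
        for c in config.categories
    ]
    or_table = pd.concat(or_rows, ignore_index=True)
    or_table["display"] = [
        f"{e:.2f} ({lo:.2f}-{hi:.2f})"
        for e, lo, hi in zip(or_table["estimate"], or_table["ci_low"], or_table["ci_high"])
    ]

    paths = {
        "adi": out / "adi.csv",
        "adjusted_rates": out / "adjusted_rates.csv",
        "or_table": out / "or_table.csv",
        "geojson": out / "region_annotated.geojson",
    }
    write_csv(adi_long, paths["adi"], digest)
    write_csv(rates, paths["adjusted_rates"], digest)
    write_csv(or_table, paths["or_table"], digest)
    export_geojson(region, tables, paths["geojson"])
    return paths
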