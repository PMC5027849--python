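"""Shared fixtures: tiny hand-built regions and random-region factories."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from localadi.calibration import StudyRegion
from localadi.variables import VARIABLE_NAMES, variable_kind


def make_profiles(values_by_unit: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Profiles with a neutral baseline, overridden per unit where stated."""
    base = {}
    for v in VARIABLE_NAMES:
        kind = variable_kind(v)
        base[v] = 50.0 if kind == "percent" else (1.0 if kind == "ratio" else 1000.0)
    rows = {}
    for uid, overrides in values_by_unit.items():
        row = dict(base)
        row.update(overrides)
        rows[uid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "unit_id"
    return df


def make_region(
    coords: dict[str, tuple[float, float]],
    profiles: pd.DataFrame | None = None,
    projected: bool = True,
    strata: tuple[str, ...] = ("young", "old"),
    pops: dict[str, tuple[float, ...]] | None = None,
) -> StudyRegion:
    ids = list(coords)
    if profiles is None:
        profiles = make_profiles({u: {} for u in ids})
    df = profiles.loc[ids].copy()
    df["x"] = [coords[u][0] for u in ids]
    df["y"] = [coords[u][1] for u in ids]
    for j, s in enumerate(strata):
        if pops is None:
            df[f"pop_{s}"] = 100.0
        else:
            df[f"pop_{s}"] = [pops[u][j] for u in ids]
    return StudyRegion(units=df, projected=projected, strata=strata)


def random_region(rng: np.random.Generator, n: int, extent_m: float = 50_000.0) -> StudyRegion:
    """Random projected region with random (range-respecting) census profiles."""
    ids = [f"U{i:03d}" for i in range(n)]
    coords = {u: (rng.uniform(0, extent_m), rng.uniform(0, extent_m)) for u in ids}
    cols = {}
    for v in VARIABLE_NAMES:
        kind = variable_kind(v)
        if kind == "percent":
            cols[v] = rng.uniform(0, 100, n)
        elif kind == "ratio":
            cols[v] = rng.uniform(0.5, 3.0, n)
        else:
            cols[v] = rng.uniform(200, 200_000, n)
    profiles = pd.DataFrame(cols, index=pd.Index(ids, name="unit_id"))
    return make_region(coords, profiles)


@pytest.fixture
def two_unit_profiles() -> pd.DataFrame:
    return make_profiles(
        {
            "A": {"pct_families_poverty": 30.0, "median_family_income": 40_000.0},
            "B": {"pct_families_poverty": 10.0, "median_family_income": 60_000.0},
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
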