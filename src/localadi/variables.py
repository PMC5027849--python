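"""Registry of the 17 census variables composing the area deprivation index.

The ADI summarizes socioeconomic disadvantage from four domains — education,
income/employment, housing, and household characteristics.  Each variable
carries a *direction*: ``+1`` when larger values indicate more deprivation
(e.g. percent of families in poverty) and ``-1`` when larger values indicate
less (e.g. median family income).  Directions are applied during
standardization so that every standardized column points toward deprivation.
"""

from __future__ import annotations

PERCENT = "percent"
CURRENCY = "currency"
RATIO = "ratio"

#: name -> (domain, direction, kind)
ADI_VARIABLES: dict[str, tuple[str, int, str]] = {
    # education
    "pct_edu_lt9y": ("education", +1, PERCENT),
    "pct_edu_hs_plus": ("education", -1, PERCENT),
    "pct_white_collar": ("education", -1, PERCENT),
    # income / employment
    "median_family_income": ("income_employment", -1, CURRENCY),
    "income_disparity": ("income_employment", +1, RATIO),
    "pct_families_poverty": ("income_employment", +1, PERCENT),
    "pct_below_150_poverty": ("income_employment", +1, PERCENT),
    "pct_unemployed": ("income_employment", +1, PERCENT),
    # housing
    "median_home_value": ("housing", -1, CURRENCY),
    "median_gross_rent": ("housing", -1, CURRENCY),
    "median_mortgage": ("housing", -1, CURRENCY),
    "pct_owner_occupied": ("housing", -1, PERCENT),
    "pct_no_plumbing": ("housing", +1, PERCENT),
    # household characteristics
    "pct_single_parent": ("household", +1, PERCENT),
    "pct_no_vehicle": ("household", +1, PERCENT),
    "pct_no_telephone": ("household", +1, PERCENT),
    "pct_crowding": ("household", +1, PERCENT),
}

VARIABLE_NAMES: tuple[str, ...] = tuple(ADI_VARIABLES)

DIRECTIONS: dict[str, int] = {v: d for v, (_, d, _) in ADI_VARIABLES.items()}


def variable_kind(name: str) -> str:
    """Return ``percent``, ``currency`` or ``ratio`` for a registered variable."""
    return ADI_VARIABLES[name][2]


def validate_profile_values(name: str, values) -> list[str]:
    """Range-check one variable column; returns a list of violation messages."""
    import numpy as np

    kind = variable_kind(name)
    arr = np.asarray(values, dtype=float)
    bad: list[str] = []
    if np.isnan(arr).any():
        bad.append(f"{name}: missing values")
    if kind == PERCENT:
        if np.nanmin(arr) < 0 or np.nanmax(arr) > 100:
            bad.append(f"{name}: percent outside [0, 100]")
    else:  # currency or ratio: non-negative
        if np.nanmin(arr) < 0:
            bad.append(f"{name}: negative value")
    return bad
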