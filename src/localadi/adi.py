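"""Raw ADI composite, percentile ranking, and top-percentile dichotomization.

The raw score of an area unit is a weighted sum of direction-adjusted
z-scores of the 17 census variables, so that higher always means more
deprived.  Percentiles use the weak-inequality rule

    percentile(u) = 100 * #{v : score(v) <= score(u)} / n

computed within an arbitrary reference set (the whole region, or a
distance-defined window); ties share the highest applicable percentile and
the maximum score is always at percentile 100.  A unit is flagged as highly
deprived when its percentile lies strictly above ``100 - threshold_pct``,
i.e. when it falls within the top ``threshold_pct`` percent of the
reference set's probability mass: with 100 unique scores and the default
threshold of 15, exactly the 15 highest-scoring units are flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .variables import DIRECTIONS, VARIABLE_NAMES

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_PCT = 15.0


@dataclass(frozen=True)
class AdiWeights:
    """Per-variable weights and deprivation directions for the composite.

    The published refinements of the ADI derive weights from a factor
    analysis whose coefficients are not redistributable; the default is
    equal weights 1/17 on direction-adjusted z-scores, and any published
    loading vector can be supplied instead.
    """

    weights: dict[str, float]
    directions: dict[str, int] = field(default_factory=lambda: dict(DIRECTIONS))

    def __post_init__(self) -> None:
        missing = set(VARIABLE_NAMES) - set(self.weights)
        extra = set(self.weights) - set(VARIABLE_NAMES)
        if missing or extra:
            raise ValueError(
                f"weights must cover exactly the 17 ADI variables; "
                f"missing={sorted(missing)}, unknown={sorted(extra)}"
            )
        if not any(w != 0 for w in self.weights.values()):
            raise ValueError("at least one weight must be nonzero")

    @classmethod
    def equal(cls) -> "AdiWeights":
        n = len(VARIABLE_NAMES)
        return cls(weights={v: 1.0 / n for v in VARIABLE_NAMES})


def standardize_variables(profiles: pd.DataFrame) -> pd.DataFrame:
    """Direction-adjusted z-scores of the 17 census variables.

    Parameters
    ----------
    profiles
        One row per area unit, columns covering the 17 canonical variable
        names (extra columns ignored).

    Returns
    -------
    DataFrame of the same index with each variable centered, scaled by its
    population (``ddof=0``) standard deviation, and multiplied by the
    variable's deprivation direction so higher always means more deprived.
    A zero-variance variable contributes 0 for every unit (logged).
    """
    missing_cols = [v for v in VARIABLE_NAMES if v not in profiles.columns]
    if missing_cols:
        raise ValueError(f"census profile columns missing: {missing_cols}")
    if len(profiles) < 2:
        raise ValueError("standardization requires at least 2 units")

    x = profiles[list(VARIABLE_NAMES)].astype(float)
    if x.isna().any().any():
        cell = x.stack()
        bad = x.isna()
        unit, var = next((i, c) for c in bad.columns for i in bad.index[bad[c]])
        raise ValueError(f"missing value for unit {unit!r}, variable {var!r}")

    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    out = pd.DataFrame(0.0, index=x.index, columns=x.columns)
    for v in VARIABLE_NAMES:
        # variance indistinguishable from float round-off counts as zero
        if sd[v] <= 1e-12 * max(1.0, abs(mean[v])):
            logger.warning("variable %s has zero variance; contributes 0 to all scores", v)
            continue
        out[v] = DIRECTIONS[v] * (x[v] - mean[v]) / sd[v]
    return out


def compute_raw_adi(profiles: pd.DataFrame, weights: AdiWeights | None = None) -> pd.Series:
    """Weighted sum of direction-adjusted standardized variables (higher = more deprived)."""
    if weights is None:
        weights = AdiWeights.equal()
    z = standardize_variables(profiles)
    w = pd.Series(weights.weights)[list(VARIABLE_NAMES)]
    score = z[list(VARIABLE_NAMES)] @ w
    score.name = "raw_score"
    return score


def percentile_rank(scores: pd.Series | np.ndarray) -> pd.Series:
    """Weak-inequality percentile: 100 * count(score <= own) / n, ties share the top rank."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("percentile_rank requires at least one score")
    if np.isnan(arr).any():
        raise ValueError("scores contain NaN")
    pct = 100.0 * rankdata(arr, method="max") / arr.size
    index = scores.index if isinstance(scores, pd.Series) else None
    return pd.Series(pct, index=index, name="percentile")


def dichotomize(percentile, threshold_pct: float = DEFAULT_THRESHOLD_PCT):
    """True when the percentile lies strictly above ``100 - threshold_pct``.

    The strict boundary makes the flagged fraction under unique scores never
    exceed the threshold (exactly ``n - floor((100 - t)/100 * n)`` units).
    A unit sitting exactly at the cut percentile is not flagged.
    """
    if not 0 < threshold_pct < 100:
        raise ValueError(f"threshold_pct must be in (0, 100), got {threshold_pct}")
    p = np.asarray(percentile, dtype=float)
    if np.any((p <= 0) | (p > 100)):
        raise ValueError("percentile must lie in (0, 100]")
    flag = p > 100.0 - threshold_pct
    if np.isscalar(percentile) or p.ndim == 0:
        return bool(flag)
    if isinstance(percentile, pd.Series):
        return pd.Series(flag, index=percentile.index, name="flag")
    return flag
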