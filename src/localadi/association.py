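"""Age-adjusted odds ratios linking dichotomized ADI exposure to hospitalization.

The validation statistic: units flagged as highly deprived form the exposed
arm, and within each age stratum a 2x2 table (hospitalized vs not) is
assembled from unit-level populations and event counts.  The stratified
tables are combined with the Mantel-Haenszel estimator,

    OR_MH = (sum_i a_i d_i / n_i) / (sum_i b_i c_i / n_i),

with the Robins-Breslow-Greenland variance for the confidence interval of
ln(OR_MH).  A crude (single-table) OR with Haldane-Anscombe 0.5 correction
and a grouped-logistic cross-check are provided alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .adi import DEFAULT_THRESHOLD_PCT, compute_raw_adi
from .calibration import DEFAULT_RADII_KM, StudyRegion, local_adi, pairwise_distance, regional_adi

logger = logging.getLogger(__name__)

STRATA_COLUMNS = ["age_stratum", "a", "b", "c", "d"]


@dataclass(frozen=True)
class OddsRatioResult:
    estimate: float
    ci_low: float
    ci_high: float
    alpha: float
    method: str  # "crude" or "mantel_haenszel"
    n_strata: int
    n_informative_strata: int

    def __post_init__(self) -> None:
        if np.isfinite([self.estimate, self.ci_low, self.ci_high]).all():
            if not self.ci_low <= self.estimate <= self.ci_high:
                raise ValueError("confidence interval does not bracket the estimate")


def build_strata(
    region: StudyRegion,
    flags: pd.Series,
    events_avg: pd.DataFrame,
    category: str = "total",
) -> pd.DataFrame:
    """Per-age-stratum 2x2 tables from unit-level flags, populations and events.

    ``a`` = events in flagged units, ``b`` = flagged population minus events,
    ``c``/``d`` likewise for unflagged units.  Units with an indeterminate
    flag contribute to neither arm (count logged).  Averaged fractional
    events are rounded half-up; counts exceeding the stratum population are
    capped with a warning.
    """
    flags = flags.reindex(region.unit_ids)
    n_na = int(flags.isna().sum())
    if n_na:
        logger.warning("build_strata: %d units with indeterminate flag excluded", n_na)
    pops = region.populations()
    ev = events_avg[events_avg["category"] == category]
    obs = (
        ev.pivot_table(index="unit_id", columns="age_stratum", values="count", fill_value=0.0)
        .reindex(index=region.unit_ids, columns=pops.columns, fill_value=0.0)
    )
    # outcome is person-level "hospitalized at least once": round half-up to integers
    obs = np.floor(obs.to_numpy(dtype=float) + 0.5)
    pop = pops.to_numpy(dtype=float)
    over = obs > pop
    if over.any():
        logger.warning("build_strata: %d (unit, stratum) event counts exceed population; capped", int(over.sum()))
        obs = np.minimum(obs, pop)

    exposed = flags.eq(True).fillna(False).to_numpy(dtype=bool)
    unexposed = flags.eq(False).fillna(False).to_numpy(dtype=bool)
    a = obs[exposed].sum(axis=0)
    b = pop[exposed].sum(axis=0) - a
    c = obs[unexposed].sum(axis=0)
    d = pop[unexposed].sum(axis=0) - c
    return pd.DataFrame(
        {"age_stratum": pops.columns, "a": a, "b": b, "c": c, "d": d}
    )


def crude_or(a: float, b: float, c: float, d: float, alpha: float = 0.05) -> OddsRatioResult:
    """Single 2x2 odds ratio ad/bc with Wald CI.

    If any cell is zero, 0.5 is added to every cell (Haldane-Anscombe)
    before both the estimate and the CI.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("2x2 cells must be >= 0")
    if (cells == 0).any():
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    est = (a_ * d_) / (b_ * c_)
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    z = norm.ppf(1 - alpha / 2)
    return OddsRatioResult(
        estimate=float(est),
        ci_low=float(est * np.exp(-z * se)),
        ci_high=float(est * np.exp(z * se)),
        alpha=alpha,
        method="crude",
        n_strata=1,
        n_informative_strata=1,
    )


def mh_or(strata: pd.DataFrame, alpha: float = 0.05) -> OddsRatioResult:
    """Mantel-Haenszel common odds ratio over age strata with RBG confidence interval.

    Strata whose margins are degenerate (an empty exposure arm or an
    all-event/no-event outcome margin) carry no information about the OR and
    are skipped; their number is reported via ``n_strata`` vs
    ``n_informative_strata``.  A zero denominator yields an infinite
    estimate with ``ci_high = inf``.
    """
    t = strata[["a", "b", "c", "d"]].to_numpy(dtype=float)
    if (t < 0).any():
        raise ValueError("2x2 cells must be >= 0")
    n_total = len(t)
    row1 = t[:, 0] + t[:, 1]  # exposed margin
    row2 = t[:, 2] + t[:, 3]
    col1 = t[:, 0] + t[:, 2]  # events margin
    col2 = t[:, 1] + t[:, 3]
    informative = (row1 > 0) & (row2 > 0) & (col1 > 0) & (col2 > 0)
    t = t[informative]
    if len(t) == 0:
        raise ValueError("no informative strata (all margins degenerate)")
    a, b, c, d = t.T
    n = a + b + c + d

    R = a * d / n
    S = b * c / n
    sum_R, sum_S = R.sum(), S.sum()
    if sum_S == 0:
        return OddsRatioResult(
            estimate=float("inf"), ci_low=float("nan"), ci_high=float("inf"),
            alpha=alpha, method="mantel_haenszel",
            n_strata=n_total, n_informative_strata=len(t),
        )
    est = sum_R / sum_S

    # Robins-Breslow-Greenland variance of ln(OR_MH)
    P = (a + d) / n
    Q = (b + c) / n
    var = (
        (P * R).sum() / (2 * sum_R**2)
        + ((P * S + Q * R).sum()) / (2 * sum_R * sum_S)
        + (Q * S).sum() / (2 * sum_S**2)
    )
    se = np.sqrt(var)
    z = norm.ppf(1 - alpha / 2)
    if est == 0 or not np.isfinite(se):
        lo, hi = float("nan"), float("nan")
    else:
        lo, hi = est * np.exp(-z * se), est * np.exp(z * se)
    return OddsRatioResult(
        estimate=float(est),
        ci_low=float(lo),
        ci_high=float(hi),
        alpha=alpha,
        method="mantel_haenszel",
        n_strata=n_total,
        n_informative_strata=len(t),
    )


def logistic_or(strata: pd.DataFrame, alpha: float = 0.05) -> tuple[float, float, float]:
    """Cross-check: exposure OR from a grouped logistic fit with stratum indicators.

    Uses iteratively reweighted least squares on the grouped binomial
    likelihood.  Returns (estimate, ci_low, ci_high).
    """
    t = strata[["a", "b", "c", "d"]].to_numpy(dtype=float)
    rows = []
    for i, (a, b, c, d) in enumerate(t):
        rows.append((i, 1.0, a, a + b))
        rows.append((i, 0.0, c, c + d))
    rows = [(s, e, y, m) for s, e, y, m in rows if m > 0]
    k = len({s for s, *_ in rows})
    X = np.zeros((len(rows), k + 1))
    y = np.zeros(len(rows))
    m = np.zeros(len(rows))
    strata_ids = sorted({s for s, *_ in rows})
    for j, (s, e, yy, mm) in enumerate(rows):
        X[j, 0] = e
        X[j, 1 + strata_ids.index(s)] = 1.0
        y[j], m[j] = yy, mm
    beta = np.zeros(k + 1)
    for _ in range(100):
        eta = X @ beta
        p = 1 / (1 + np.exp(-eta))
        w = m * p * (1 - p)
        w = np.maximum(w, 1e-10)
        z_work = eta + (y - m * p) / w
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z_work))
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    p = 1 / (1 + np.exp(-eta))
    w = np.maximum(m * p * (1 - p), 1e-10)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = np.sqrt(cov[0, 0])
    z = norm.ppf(1 - alpha / 2)
    est = float(np.exp(beta[0]))
    return est, float(np.exp(beta[0] - z * se)), float(np.exp(beta[0] + z * se))


def compare_scales(
    region: StudyRegion,
    raw_scores: pd.Series | None,
    events_avg: pd.DataFrame,
    category: str = "total",
    radii: tuple[float, ...] = DEFAULT_RADII_KM,
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
    min_window: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One odds ratio per calibration scale — local(r) for each radius, then regional.

    The analogue of the scale-comparison table: identical events and outcome
    definition across scales, only the exposure flag changes.
    """
    from .calibration import DEFAULT_MIN_WINDOW

    if raw_scores is None:
        raw_scores = compute_raw_adi(region.profiles())
    if min_window is None:
        min_window = DEFAULT_MIN_WINDOW
    distances = pairwise_distance(region)
    rows = []
    for r in radii:
        res = local_adi(region, raw_scores, r, threshold_pct, min_window=min_window, distances=distances)
        rows.append((f"local_{r:g}km", res["flag"]))
    rows.append(("regional", regional_adi(region, raw_scores, threshold_pct)["flag"]))

    out = []
    for scale, flags in rows:
        strata = build_strata(region, flags, events_avg, category)
        orr = mh_or(strata, alpha=alpha)
        out.append(
            {
                "scale": scale,
                "category": category,
                "estimate": orr.estimate,
                "ci_low": orr.ci_low,
                "ci_high": orr.ci_high,
                "n_strata": orr.n_strata,
                "n_informative_strata": orr.n_informative_strata,
                "n_flagged": int(flags.eq(True).fillna(False).sum()),
                "n_indeterminate": int(flags.isna().sum()),
            }
        )
    return pd.DataFrame(out)
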