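"""Stratified 2x2 assembly, crude and Mantel-Haenszel odds ratios."""

import numpy as np
import pandas as pd
import pytest

from localadi import build_strata, crude_or, mh_or
from localadi.association import logistic_or

from conftest import make_region


def strata_frame(*tables):
    return pd.DataFrame(
        [{"age_stratum": f"s{i}", "a": a, "b": b, "c": c, "d": d} for i, (a, b, c, d) in enumerate(tables)]
    )


class TestBuildStrata:
    def test_direct_assembly_one_stratum(self):
        r = make_region(
            {"F": (0.0, 0.0), "U": (1000.0, 0.0)},
            strata=("all",),
            pops={"F": (100.0,), "U": (100.0,)},
        )
        events = pd.DataFrame(
            {"unit_id": ["F", "U"], "age_stratum": ["all", "all"],
             "category": ["total", "total"], "count": [10.0, 5.0]}
        )
        flags = pd.Series(pd.array([True, False], dtype="boolean"), index=["F", "U"])
        t = build_strata(r, flags, events)
        assert t[["a", "b", "c", "d"]].iloc[0].tolist() == [10.0, 90.0, 5.0, 95.0]

    def test_indeterminate_flag_contributes_to_neither_arm(self):
        r = make_region(
            {"F": (0.0, 0.0), "U": (1000.0, 0.0), "N": (2000.0, 0.0)},
            strata=("all",),
            pops={"F": (100.0,), "U": (100.0,), "N": (100.0,)},
        )
        events = pd.DataFrame(
            {"unit_id": ["F", "U", "N"], "age_stratum": ["all"] * 3,
             "category": ["total"] * 3, "count": [10.0, 5.0, 50.0]}
        )
        flags = pd.Series(pd.array([True, False, None], dtype="boolean"), index=["F", "U", "N"])
        t = build_strata(r, flags, events)
        assert t[["a", "b", "c", "d"]].iloc[0].tolist() == [10.0, 90.0, 5.0, 95.0]

    def test_fractional_counts_rounded_half_up_and_capped(self, caplog):
        r = make_region(
            {"F": (0.0, 0.0), "U": (1000.0, 0.0)},
            strata=("all",),
            pops={"F": (100.0,), "U": (10.0,)},
        )
        events = pd.DataFrame(
            {"unit_id": ["F", "U"], "age_stratum": ["all", "all"],
             "category": ["total", "total"], "count": [2.5, 99.0]}
        )
        flags = pd.Series(pd.array([True, False], dtype="boolean"), index=["F", "U"])
        with caplog.at_level("WARNING", logger="localadi.association"):
            t = build_strata(r, flags, events)
        assert t["a"].iloc[0] == 3.0  # 2.5 rounds half-up
        assert t["c"].iloc[0] == 10.0  # capped at population
        assert any("capped" in rec.message for rec in caplog.records)

    def test_matches_per_unit_accumulation_oracle(self, rng):
        n = 30
        ids = [f"U{i}" for i in range(n)]
        coords = {u: (rng.uniform(0, 1e4), rng.uniform(0, 1e4)) for u in ids}
        pops = {u: (float(rng.integers(50, 300)), float(rng.integers(50, 300))) for u in ids}
        r = make_region(coords, strata=("young", "old"), pops=pops)
        rows = []
        for u in ids:
            for j, s in enumerate(("young", "old")):
                rows.append({"unit_id": u, "age_stratum": s, "category": "total",
                             "count": float(rng.integers(0, 20))})
        events = pd.DataFrame(rows)
        flag_vals = rng.random(n) < 0.3
        flags = pd.Series(pd.array(flag_vals, dtype="boolean"), index=ids)
        t = build_strata(r, flags, events).set_index("age_stratum")

        def unit_count(u, s):
            m = (events["unit_id"] == u) & (events["age_stratum"] == s)
            return float(events.loc[m, "count"].sum())

        for j, s in enumerate(("young", "old")):
            a = sum(unit_count(u, s) for u in ids if flags[u])
            b = sum(pops[u][j] for u in ids if flags[u]) - a
            c = sum(unit_count(u, s) for u in ids if not flags[u])
            d = sum(pops[u][j] for u in ids if not flags[u]) - c
            assert t.loc[s, ["a", "b", "c", "d"]].tolist() == [a, b, c, d]


class TestCrudeOr:
    def test_hand_example(self):
        r = crude_or(10, 90, 5, 95)
        assert r.estimate == pytest.approx(10 * 95 / (90 * 5))  # 2.111...
        assert r.ci_low < r.estimate < r.ci_high

    def test_symmetric_table_is_one(self):
        for k in (1, 5, 50):
            assert crude_or(k, k, k, k).estimate == pytest.approx(1.0)

    def test_haldane_correction_on_zero_cell(self):
        r = crude_or(0, 10, 5, 5)
        assert r.estimate == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))  # 0.047619...
        assert np.isfinite(r.ci_low) and np.isfinite(r.ci_high)

    def test_arm_exchange_inverts(self):
        fwd = crude_or(12, 88, 7, 93)
        rev = crude_or(7, 93, 12, 88)
        assert rev.estimate == pytest.approx(1 / fwd.estimate)
        assert rev.ci_low == pytest.approx(1 / fwd.ci_high)
        assert rev.ci_high == pytest.approx(1 / fwd.ci_low)


class TestMantelHaenszel:
    def test_single_stratum_equals_crude(self):
        s = strata_frame((10, 90, 5, 95))
        assert mh_or(s).estimate == crude_or(10, 90, 5, 95).estimate

    def test_replicated_stratum_leaves_estimate_unchanged(self):
        one = mh_or(strata_frame((10, 90, 5, 95)))
        two = mh_or(strata_frame((10, 90, 5, 95), (10, 90, 5, 95)))
        assert two.estimate == pytest.approx(one.estimate)
        # more data -> narrower interval
        assert (two.ci_high - two.ci_low) < (one.ci_high - one.ci_low)

    def test_two_stratum_hand_arithmetic(self):
        # (10*95/200 + 20*90/200) / (90*5/200 + 80*10/200) = 13.75 / 6.25 = 2.2
        r = mh_or(strata_frame((10, 90, 5, 95), (20, 80, 10, 90)))
        assert r.estimate == pytest.approx(2.2, abs=1e-12)
        assert r.n_informative_strata == 2

    def test_estimate_within_stratum_or_range(self, rng):
        for _ in range(30):
            tables = [tuple(rng.integers(1, 60, 4)) for _ in range(4)]
            stratum_ors = [a * d / (b * c) for a, b, c, d in tables]
            est = mh_or(strata_frame(*tables)).estimate
            assert min(stratum_ors) - 1e-12 <= est <= max(stratum_ors) + 1e-12

    def test_arm_exchange_inverts(self):
        s = strata_frame((10, 90, 5, 95), (20, 80, 10, 90))
        swapped = strata_frame((5, 95, 10, 90), (10, 90, 20, 80))
        fwd, rev = mh_or(s), mh_or(swapped)
        assert rev.estimate == pytest.approx(1 / fwd.estimate)
        assert rev.ci_low == pytest.approx(1 / fwd.ci_high)

    def test_integer_scaling_invariance(self):
        s = strata_frame((10, 90, 5, 95), (20, 80, 10, 90))
        scaled = strata_frame((30, 270, 15, 285), (60, 240, 30, 270))
        assert mh_or(scaled).estimate == pytest.approx(mh_or(s).estimate)

    def test_noninformative_strata_skipped_and_counted(self):
        s = strata_frame((10, 90, 5, 95), (0, 0, 3, 97))
        r = mh_or(s)
        assert r.n_strata == 2
        assert r.n_informative_strata == 1
        assert r.estimate == pytest.approx(crude_or(10, 90, 5, 95).estimate)

    def test_all_noninformative_rejected(self):
        with pytest.raises(ValueError, match="informative"):
            mh_or(strata_frame((0, 0, 5, 95)))

    def test_zero_denominator_reports_infinite(self):
        r = mh_or(strata_frame((10, 90, 0, 100)))
        assert np.isinf(r.estimate)
        assert np.isinf(r.ci_high)

    def test_agrees_with_statsmodels_stratified_table(self, rng):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        for _ in range(10):
            tables = [rng.integers(1, 80, 4) for _ in range(5)]
            s = strata_frame(*[tuple(t) for t in tables])
            ours = mh_or(s)
            arr = np.array([[[a, b], [c, d]] for a, b, c, d in tables]).transpose(1, 2, 0)
            ref = sm.StratifiedTable(arr.astype(float))
            assert ours.estimate == pytest.approx(ref.oddsratio_pooled, rel=1e-10)
            lo, hi = ref.oddsratio_pooled_confint(0.05)
            assert ours.ci_low == pytest.approx(lo, rel=1e-6)
            assert ours.ci_high == pytest.approx(hi, rel=1e-6)

    def test_grouped_logistic_cross_check_is_close(self):
        s = strata_frame((40, 960, 25, 975), (80, 920, 45, 955), (120, 880, 70, 930))
        mh = mh_or(s)
        est, lo, hi = logistic_or(s)
        assert est == pytest.approx(mh.estimate, rel=0.02)
        assert lo < est < hi
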