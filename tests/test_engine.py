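"""Parameter synthesis: batch operations, the running summary, and their contract."""

import math

import numpy as np
import pytest

from cmparams import (
    CMSeries,
    RunningSummary,
    TargetSpec,
    batch_derive,
    compute_abn_auc,
    compute_auc,
    compute_chronicity,
    compute_lability,
    compute_refractoriness,
    compute_time_wt_avg,
    compute_trends,
    detect_clusters,
    incremental_derive,
)
from conftest import random_series


def _approx(a, b, rel=1e-9):
    if a is None or b is None:
        return a is None and b is None
    return math.isclose(a, b, rel_tol=rel, abs_tol=1e-12)


class TestBurden:
    def test_auc_worked_example(self, worked_series):
        assert compute_auc(worked_series) == pytest.approx(4425.0)

    def test_auc_rectangle_and_single(self):
        s = CMSeries.from_pairs("p", "SBP", [(0, 120.0), (50, 120.0)])
        assert compute_auc(s) == pytest.approx(120.0 * 50)
        assert compute_auc(CMSeries.from_pairs("p", "SBP", [(0, 120.0)])) is None

    def test_abn_auc_worked_example(self, worked_series, sbp_target):
        assert compute_abn_auc(worked_series, sbp_target) == pytest.approx(300.0)

    def test_abn_auc_at_goal_and_constant_excess(self, sbp_target):
        s = CMSeries.from_pairs("p", "SBP", [(0, 120.0), (10, 130.0), (30, 125.0)])
        assert compute_abn_auc(s, sbp_target) == pytest.approx(0.0)
        s2 = CMSeries.from_pairs("p", "SBP", [(0, 150.0), (10, 150.0)])
        assert compute_abn_auc(s2, sbp_target) == pytest.approx(100.0)

    def test_time_wt_avg(self, worked_series):
        assert compute_time_wt_avg(worked_series) == pytest.approx(147.5)
        lin = CMSeries.from_pairs("p", "SBP", [(0, 100.0), (10, 200.0)])
        assert compute_time_wt_avg(lin) == pytest.approx(150.0)
        const = CMSeries.from_pairs("p", "SBP", [(0, 120.0), (7, 120.0), (40, 120.0)])
        assert compute_time_wt_avg(const) == pytest.approx(120.0)

    def test_time_wt_avg_abnormal_numerator_mode(self, worked_series, sbp_target):
        assert compute_time_wt_avg(worked_series, sbp_target, on="abn_auc") == pytest.approx(10.0)

    def test_time_wt_avg_within_value_range(self, series_factory):
        rng = np.random.default_rng(11)
        for _ in range(50):
            s = series_factory(rng, min_n=2)
            twa = compute_time_wt_avg(s)
            v = s.values
            assert v.min() - 1e-9 <= twa <= v.max() + 1e-9


class TestChronicity:
    def test_worked_example(self, worked_series, sbp_target):
        assert compute_chronicity(worked_series, sbp_target) == (10, 2)

    def test_all_normal_and_all_abnormal(self, sbp_target):
        normal = CMSeries.from_pairs("p", "SBP", [(0, 120.0), (10, 125.0)])
        assert compute_chronicity(normal, sbp_target) == (0, 0)
        abn = CMSeries.from_pairs("p", "SBP", [(0, 150.0), (10, 150.0), (30, 150.0)])
        assert compute_chronicity(abn, sbp_target) == (30, 3)


class TestClusters:
    def test_worked_example_one_closed_cluster(self, worked_series, sbp_target):
        (c,) = detect_clusters(worked_series, sbp_target)
        assert (c.start_day, c.last_abnormal_day, c.count, c.open) == (10, 20, 2, False)

    def test_abnormal_first_reading_opens_cluster(self, sbp_target):
        s = CMSeries.from_pairs("p", "SBP", [(0, 150.0), (10, 130.0), (20, 150.0)])
        c1, c2 = detect_clusters(s, sbp_target)
        assert (c1.count, c1.open) == (1, False)
        assert (c2.count, c2.open) == (1, True)

    def test_all_normal_no_clusters(self, sbp_target):
        s = CMSeries.from_pairs("p", "SBP", [(0, 120.0), (10, 125.0)])
        assert detect_clusters(s, sbp_target) == []


class TestRefractoriness:
    def test_closed_cluster_only_gives_max_days(self, worked_series, sbp_target):
        clusters = detect_clusters(worked_series, sbp_target)
        assert compute_refractoriness(clusters, last_reading_abnormal=False) == (None, None, 10)

    def test_open_cluster_fields(self, sbp_target):
        s = CMSeries.from_pairs("p", "SBP", [(0, 130.0), (10, 150.0), (25, 160.0)])
        clusters = detect_clusters(s, sbp_target)
        assert compute_refractoriness(clusters, last_reading_abnormal=True) == (15, 2, 15)

    def test_isolated_singletons_all_missing(self, sbp_target):
        s = CMSeries.from_pairs(
            "p", "SBP", [(0, 150.0), (10, 120.0), (20, 150.0), (30, 120.0)]
        )
        clusters = detect_clusters(s, sbp_target)
        assert compute_refractoriness(clusters, last_reading_abnormal=False) == (None, None, None)

    def test_inconsistent_state_is_an_engine_bug(self):
        with pytest.raises(RuntimeError):
            compute_refractoriness([], last_reading_abnormal=True)


class TestLabilityAndTrends:
    def test_worked_example(self, worked_series):
        cv, mvd = compute_lability(worked_series)
        assert cv == pytest.approx(0.09578, abs=5e-6)
        assert mvd == pytest.approx(55.0 / 3.0)
        nc, l3 = compute_trends(worked_series)
        assert nc == pytest.approx(5.0)
        assert l3 == pytest.approx(-0.0795454545, abs=1e-9)

    def test_constant_series_no_dispersion(self):
        s = CMSeries.from_pairs("p", "SBP", [(0, 100.0), (10, 100.0), (20, 100.0), (30, 100.0)])
        assert compute_lability(s) == (0.0, 0.0)
        assert compute_trends(s) == (0.0, 0.0)

    def test_single_reading_missing(self):
        s = CMSeries.from_pairs("p", "SBP", [(0, 100.0)])
        assert compute_lability(s) == (None, None)
        nc, l3 = compute_trends(s)
        assert nc == 0.0 and l3 is None

    def test_three_readings_lag3_missing(self):
        s = CMSeries.from_pairs("p", "SBP", [(0, 100.0), (10, 105.0), (20, 103.0)])
        assert compute_trends(s)[1] is None


class TestRunningSummary:
    def test_single_normal_reading(self, sbp_target):
        s = RunningSummary()
        from cmparams import Reading

        s.update(Reading(0, 130.0), sbp_target)
        assert s.n == 1 and s.last_value == 130.0 and s.num_clust == 0

    def test_cluster_transitions_trace(self, sbp_target):
        from cmparams import Reading

        s = RunningSummary()
        for d, v in [(0, 130.0), (10, 150.0), (20, 160.0)]:
            s.update(Reading(d, v), sbp_target)
        c = s.current_cluster
        assert (c.start_day, c.last_abnormal_day, c.count, c.open) == (10, 20, 2, True)
        s.update(Reading(30, 135.0), sbp_target)
        assert s.current_cluster is None
        assert s.num_clust == 1 and s.max_closed_clust_days == 10

    def test_out_of_order_append_rejected(self, sbp_target):
        from cmparams import Reading

        s = RunningSummary()
        s.update(Reading(10, 130.0), sbp_target)
        with pytest.raises(ValueError):
            s.update(Reading(5, 130.0), sbp_target)

    def test_finalize_single_reading(self, sbp_target):
        from cmparams import Reading

        pv = RunningSummary().update(Reading(0, 130.0), sbp_target).finalize()
        assert pv.value1 == 130.0 and pv.num_not_at_goal == 0 and pv.net_change == 0.0
        for f in ("fu_days_not_at_goal", "abn_auc", "time_wt_avg", "coeff_var",
                  "mean_val_diff", "lag3_dev", "time_not_at_goal", "ct_not_at_goal",
                  "max_clust_days"):
            assert getattr(pv, f) is None, f

    def test_empty_summary_all_missing(self):
        pv = RunningSummary().finalize()
        assert all(v is None for v in pv.as_dict().values())

    def test_vector_has_13_slots(self, worked_series, sbp_target):
        pv = batch_derive(worked_series, sbp_target)
        assert len(pv.as_dict()) == 13


class TestWorkedExampleVector:
    def test_all_13_parameters(self, worked_series, sbp_target):
        pv = batch_derive(worked_series, sbp_target).as_dict()
        assert pv["Value1"] == 135.0
        assert pv["FUDaysNotAtGoal"] == 10
        assert pv["NumNotAtGoal"] == 2
        assert pv["AbnAUC"] == pytest.approx(300.0)
        assert pv["TimeWtAvg"] == pytest.approx(147.5)
        assert pv["TimeNotAtGoal"] is None
        assert pv["CtNotAtGoal"] is None
        assert pv["MaxClustDays"] == 10
        assert pv["NumClust"] == 1
        assert pv["CoeffVar"] == pytest.approx(0.09578, abs=5e-6)
        assert pv["MeanValDiff"] == pytest.approx(18.3333333, abs=1e-6)
        assert pv["NetChange"] == pytest.approx(5.0)
        assert pv["Lag3Dev"] == pytest.approx(-35.0 / 3.0 / (440.0 / 3.0), abs=1e-12)


class TestIncrementalBatchContract:
    def test_worked_example_identical(self, worked_series, sbp_target):
        assert _dicts_match(
            incremental_derive(worked_series, sbp_target).as_dict(),
            batch_derive(worked_series, sbp_target).as_dict(),
        )

    def test_random_series_agree(self):
        """Fold-of-update then finalize equals the batch recomputation."""
        rng = np.random.default_rng(20260924)
        target = TargetSpec("SBP", high=140.0)
        for i in range(1000):
            s = random_series(rng, patient_id=f"p{i}")
            inc = incremental_derive(s, target).as_dict()
            bat = batch_derive(s, target).as_dict()
            assert _dicts_match(inc, bat), (i, inc, bat)

    def test_two_sided_target_agrees(self):
        rng = np.random.default_rng(5)
        target = TargetSpec("HCT", low=38.0, high=52.0)
        for i in range(200):
            n = int(rng.integers(0, 40))
            days = np.cumsum(rng.integers(1, 60, size=n))
            vals = 45.0 + rng.normal(0, 6, size=n)
            s = CMSeries.from_pairs(f"p{i}", "HCT", list(zip(days, vals)))
            assert _dicts_match(
                incremental_derive(s, target).as_dict(), batch_derive(s, target).as_dict()
            )


def _dicts_match(a, b, rel=1e-9):
    int_fields = {"FUDaysNotAtGoal", "NumNotAtGoal", "TimeNotAtGoal", "CtNotAtGoal",
                  "MaxClustDays", "NumClust"}
    for k in a:
        x, y = a[k], b[k]
        if x is None or y is None:
            if not (x is None and y is None):
                return False
        elif k in int_fields:
            if x != y:
                return False
        elif not math.isclose(x, y, rel_tol=rel, abs_tol=1e-12):
            return False
    return True


class TestInvariantsAndEquivariance:
    def test_scale_equivariance(self, series_factory):
        """v -> c*v with bounds scaled multiplies unit-bearing parameters by c."""
        rng = np.random.default_rng(17)
        c = 2.5
        for i in range(25):
            s = series_factory(rng, min_n=4)
            t = TargetSpec("SBP", high=140.0)
            tc = TargetSpec("SBP", high=140.0 * c)
            sc = CMSeries.from_pairs(s.patient_id, "SBP",
                                     [(r.day, r.value * c) for r in s.readings])
            pv, pvc = batch_derive(s, t).as_dict(), batch_derive(sc, tc).as_dict()
            for name in ("Value1", "TimeWtAvg", "MeanValDiff", "NetChange", "AbnAUC"):
                assert pvc[name] == pytest.approx(c * pv[name], rel=1e-9)
            for name in ("CoeffVar", "Lag3Dev", "FUDaysNotAtGoal", "NumNotAtGoal",
                         "NumClust", "MaxClustDays", "TimeNotAtGoal", "CtNotAtGoal"):
                if pv[name] is None:
                    assert pvc[name] is None
                else:
                    assert pvc[name] == pytest.approx(pv[name], rel=1e-9)

    def test_order_bounds(self, series_factory, sbp_target):
        rng = np.random.default_rng(23)
        for i in range(50):
            s = series_factory(rng, min_n=2)
            pv = batch_derive(s, sbp_target).as_dict()
            v = s.values
            assert v.min() - 1e-9 <= pv["TimeWtAvg"] <= v.max() + 1e-9
            assert pv["NumClust"] <= pv["NumNotAtGoal"] or pv["NumNotAtGoal"] == 0
            if pv["CtNotAtGoal"] is not None:
                assert pv["CtNotAtGoal"] <= pv["NumNotAtGoal"]
            if pv["MaxClustDays"] is not None:
                assert pv["MaxClustDays"] <= pv["FUDaysNotAtGoal"]

    def test_constant_at_goal_series(self, sbp_target):
        s = CMSeries.from_pairs("p", "SBP", [(0, 120.0), (30, 120.0), (90, 120.0)])
        pv = batch_derive(s, sbp_target).as_dict()
        assert pv["FUDaysNotAtGoal"] == 0 and pv["NumNotAtGoal"] == 0
        assert pv["AbnAUC"] == 0.0 and pv["NumClust"] == 0
        assert pv["CoeffVar"] == 0.0 and pv["MeanValDiff"] == 0.0 and pv["NetChange"] == 0.0

    def test_collinear_insertion_preserves_time_wt_avg(self, sbp_target):
        """Readings inserted on the segment between two visits leave the
        time-weighted average unchanged while moving the raw mean --
        the sampling-bias robustness claim at the level where it is exact."""
        s = CMSeries.from_pairs("p", "SBP", [(0, 120.0), (100, 170.0), (200, 120.0)])
        dense_pairs = [(0, 120.0)]
        for d in (20, 40, 60, 80):
            dense_pairs.append((d, 120.0 + 0.5 * d))
        dense_pairs += [(100, 170.0), (200, 120.0)]
        dense = CMSeries.from_pairs("p", "SBP", dense_pairs)
        assert compute_time_wt_avg(dense) == pytest.approx(compute_time_wt_avg(s), rel=1e-12)
        assert dense.values.mean() > s.values.mean()  # raw mean drawn toward the dense side
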