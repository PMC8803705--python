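"""State segmentation: baselines, bout detection, taxonomy, strategies."""

import datetime as dt
import warnings

import numpy as np
import pandas as pd
import pytest

from heterotherm import classifier as cls

SUNRISE = dt.time(6, 0)
SUNSET = dt.time(18, 30)
DAY = dt.date(2019, 6, 1)


def _mr_frame(bouts=(), depth=0.7, start="2019-06-01 05:00", hours=15.0):
    """Flat MR of 1.0 with square-wave depressions over the given spans."""
    idx = pd.date_range(start, periods=int(hours * 360), freq="10s")
    mr = np.ones(len(idx))
    for t0, t1 in bouts:
        m = (idx >= pd.Timestamp(t0)) & (idx < pd.Timestamp(t1))
        mr[m] = 1.0 - depth
    return pd.DataFrame({"timestamp": idx, "mr_ml_g_h": mr})


def _windows():
    return [cls.resting_window(DAY, sunrise_override=SUNRISE, sunset_override=SUNSET)]


def _segment(mr_df, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cls.segment_run(mr_df, _windows(), **kw)


class TestRestingWindow:
    def test_window_is_sunrise_to_sunset_minus_30(self):
        w = _windows()[0]
        assert w.start == dt.datetime.combine(DAY, dt.time(6, 0))
        assert w.end == dt.datetime.combine(DAY, dt.time(18, 0))

    def test_needs_coordinates_or_overrides(self):
        with pytest.raises(ValueError):
            cls.resting_window(DAY)

    def test_solar_coordinates_accepted(self):
        w = cls.resting_window(DAY, latitude=-24.05, longitude=43.75,
                               utc_offset_hours=3.0)
        assert w.start.date() == DAY and w.start < w.end


class TestLowestFraction:
    def test_floor_rule(self):
        vals = np.array([5.0, 1.0, 4.0, 2.0, 3.0])
        hours = np.zeros(5)
        keep = cls.lowest_fraction_mask(vals, hours, 0.5)
        # floor(0.5·5) = 2 lowest values
        assert sorted(vals[keep]) == [1.0, 2.0]

    def test_ties_stable(self):
        vals = np.array([1.0, 1.0, 1.0, 2.0])
        keep = cls.lowest_fraction_mask(vals, np.zeros(4), 0.5)
        assert list(np.flatnonzero(keep)) == [0, 1]

    def test_at_least_one_kept(self):
        keep = cls.lowest_fraction_mask(np.array([3.0]), np.zeros(1), 0.5)
        assert keep.sum() == 1

    def test_sparse_hours_skipped_with_warning(self):
        vals = np.arange(4.0)
        with pytest.warns(UserWarning, match="skipped"):
            keep = cls.lowest_fraction_mask(vals, np.zeros(4), 0.5, min_retained=6)
        assert not keep.any()


class TestDetectTorpor:
    def test_threshold_inclusive(self):
        mask = cls.detect_torpor(np.array([0.5, 0.51, 0.49]), 1.0, 0.5)
        assert list(mask) == [True, False, True]


class TestSegmentation:
    def test_single_micro_bout(self):
        df = _mr_frame([("2019-06-01 10:00", "2019-06-01 10:30")])
        seg = _segment(df)
        assert len(seg.bouts) == 1
        b = seg.bouts[0]
        assert b.bout_type == cls.MICRO
        assert b.duration_min == pytest.approx(30.0, abs=0.2)
        assert seg.rmr_baseline.value == pytest.approx(1.0, abs=1e-9)

    def test_sub_five_minute_runs_are_noise(self):
        df = _mr_frame([("2019-06-01 10:00", "2019-06-01 10:04")])
        seg = _segment(df)
        assert seg.bouts == []

    def test_gap_merging(self):
        # two sub-threshold runs separated by 2 supra-threshold samples merge
        df = _mr_frame([("2019-06-01 10:00:00", "2019-06-01 10:10:00"),
                        ("2019-06-01 10:10:20", "2019-06-01 10:20:00")])
        seg = _segment(df)
        assert len(seg.bouts) == 1
        assert seg.bouts[0].duration_min == pytest.approx(20.0, abs=0.2)
        # ...but the bridged samples stay labelled REST
        bridged = (df["timestamp"] >= pd.Timestamp("2019-06-01 10:10:00")) & (
            df["timestamp"] < pd.Timestamp("2019-06-01 10:10:20"))
        assert (seg.labels[bridged.to_numpy()] == cls.REST).all()

    def test_longer_gap_splits(self):
        df = _mr_frame([("2019-06-01 10:00:00", "2019-06-01 10:10:00"),
                        ("2019-06-01 10:11:00", "2019-06-01 10:21:00")])
        seg = _segment(df)
        assert len(seg.bouts) == 2

    def test_extended_bout_classified(self):
        df = _mr_frame([("2019-06-01 09:00", "2019-06-01 13:00")], depth=0.84)
        seg = _segment(df)
        assert [b.bout_type for b in seg.bouts] == [cls.EXTENDED]

    def test_sixty_minute_boundary_is_extended(self):
        df = _mr_frame([("2019-06-01 10:00", "2019-06-01 11:00")])
        seg = _segment(df)
        assert seg.bouts[0].duration_min >= 60.0
        assert seg.bouts[0].bout_type == cls.EXTENDED

    def test_tmr_matches_configured_depth(self):
        df = _mr_frame([("2019-06-01 09:00", "2019-06-01 13:00")], depth=0.8)
        seg = _segment(df)
        assert seg.bouts[0].mean_tmr == pytest.approx(0.2, abs=1e-6)

    def test_stress_window_excluded(self):
        df = _mr_frame()
        seg = _segment(df)
        first30 = df["timestamp"] < pd.Timestamp("2019-06-01 05:30")
        assert (seg.labels[first30.to_numpy()] == cls.EXCLUDED_STRESS).all()

    def test_feeding_exclusion(self):
        df = _mr_frame()
        seg = _segment(df, feeding_times=[dt.datetime(2019, 6, 1, 12, 0)])
        window = (df["timestamp"] >= pd.Timestamp("2019-06-01 12:00")) & (
            df["timestamp"] < pd.Timestamp("2019-06-01 15:00"))
        assert (seg.labels[window.to_numpy()] == cls.EXCLUDED_FEEDING).all()

    def test_labels_partition(self):
        df = _mr_frame([("2019-06-01 10:00", "2019-06-01 10:30"),
                        ("2019-06-01 09:00", "2019-06-01 09:10")])
        seg = _segment(df)
        known = {cls.REST, cls.ACTIVE, cls.MICRO_TORPOR, cls.EXTENDED_TORPOR,
                 cls.MULTIDAY_TORPOR, cls.ENTRY, cls.AROUSAL,
                 cls.EXCLUDED_FEEDING, cls.EXCLUDED_STRESS}
        assert len(seg.labels) == len(df)
        assert set(seg.labels) <= known

    def test_torpid_labels_truly_subthreshold(self):
        df = _mr_frame([("2019-06-01 10:00", "2019-06-01 10:30")])
        seg = _segment(df)
        torp = seg.labels.isin([cls.MICRO_TORPOR, cls.EXTENDED_TORPOR,
                                cls.MULTIDAY_TORPOR]).to_numpy()
        thr = 0.5 * seg.rmr_baseline.value
        assert (df["mr_ml_g_h"].to_numpy()[torp] <= thr).all()

    def test_no_resting_samples_raises(self):
        idx = pd.date_range("2019-06-01 19:00", periods=100, freq="10s")
        df = pd.DataFrame({"timestamp": idx, "mr_ml_g_h": np.ones(100)})
        with pytest.raises(ValueError):
            cls.segment_run(df, _windows())


class TestTskinConfirmation:
    @staticmethod
    def _tskin(delta):
        idx = pd.date_range("2019-06-01 05:00", periods=15 * 12, freq="5min")
        t = np.full(len(idx), 36.5)
        m = (idx >= pd.Timestamp("2019-06-01 09:00")) & (idx < pd.Timestamp("2019-06-01 13:00"))
        t[m] += delta
        return pd.DataFrame({"timestamp": idx, "t_skin_c": t})

    @pytest.mark.parametrize("delta", [-2.9, 2.9])
    def test_sign_agnostic_confirmation(self, delta):
        df = _mr_frame([("2019-06-01 09:00", "2019-06-01 13:00")], depth=0.84)
        seg = _segment(df, t_skin=self._tskin(delta))
        assert seg.bouts[0].tskin_confirmed is True
        assert seg.bouts[0].delta_tskin == pytest.approx(delta, abs=0.3)

    def test_small_deviation_warns_but_keeps_bout(self):
        df = _mr_frame([("2019-06-01 09:00", "2019-06-01 13:00")], depth=0.84)
        with pytest.warns(UserWarning, match="criterion"):
            seg = cls.segment_run(df, _windows(), t_skin=self._tskin(0.5))
        assert seg.bouts[0].bout_type == cls.EXTENDED
        assert seg.bouts[0].tskin_confirmed is False

    def test_missing_tskin_falls_back_to_duration(self):
        df = _mr_frame([("2019-06-01 09:00", "2019-06-01 13:00")], depth=0.84)
        with pytest.warns(UserWarning, match="duration only"):
            seg = cls.segment_run(df, _windows())
        assert seg.bouts[0].tskin_confirmed is None


class TestStrategies:
    @staticmethod
    def _bouts(types):
        return pd.DataFrame({"bout_type": list(types)})

    def test_classify_strategy(self):
        assert cls.classify_strategy(self._bouts([])) == cls.EUTHERMIC
        assert cls.classify_strategy(self._bouts(["MICRO"])) == cls.MICRO_ONLY
        assert cls.classify_strategy(self._bouts(["EXTENDED"])) == cls.EXTENDED_ONLY
        assert cls.classify_strategy(self._bouts(["MICRO", "EXTENDED"])) == cls.MICRO_PLUS_EXTENDED
        assert cls.classify_strategy(self._bouts(["MULTIDAY"])) == cls.EXTENDED_ONLY

    def test_strategy_table_reports_boutless_days(self):
        bt = pd.DataFrame(
            {"animal_id": ["a"], "date": [DAY], "bout_type": ["MICRO"],
             "duration_min": [10.0]}
        )
        days = [("a", DAY), ("a", DAY + dt.timedelta(days=1))]
        tbl = cls.strategy_table(bt, days)
        assert list(tbl["strategy"]) == [cls.MICRO_ONLY, cls.EUTHERMIC]

    def test_daily_metrics(self):
        bt = pd.DataFrame(
            {
                "animal_id": ["a", "a", "a"],
                "date": [DAY] * 3,
                "bout_type": ["MICRO", "MICRO", "EXTENDED"],
                "duration_min": [10.0, 20.0, 300.0],
            }
        )
        d = cls.daily_metrics(bt).iloc[0]
        assert d["micro_count"] == 2
        assert d["micro_mean_duration_min"] == 15.0
        assert d["extended_total_min"] == 300.0
        assert d["total_torpid_min"] == 330.0
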