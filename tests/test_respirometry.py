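"""Raw-trace validation, drift correction and the flow equation."""

import numpy as np
import pandas as pd
import pytest

from heterotherm import respirometry as resp


def _meta(**kw):
    base = dict(flow_lph=50.0, bm_pre_g=51.0, bm_post_g=49.0, animal_id="a1")
    base.update(kw)
    return resp.RunMetadata(**base)


def _trace(o2, segment=None, start="2019-06-01 10:00:00", cadence_s=10):
    n = len(o2)
    idx = pd.date_range(start, periods=n, freq=f"{cadence_s}s")
    seg = segment if segment is not None else [resp.SAMPLE] * n
    return resp.RawO2Trace(
        data=pd.DataFrame({"timestamp": idx, "o2_fraction": o2, "segment": seg}),
        flow_lph=50.0,
    )


class TestMetadata:
    def test_body_mass_is_pre_post_mean(self):
        assert _meta().body_mass_g == 50.0

    def test_invalid_rq_rejected(self):
        with pytest.raises(ValueError):
            _meta(rq=0.5)

    def test_nonpositive_flow_rejected(self):
        with pytest.raises(ValueError):
            _meta(flow_lph=0.0)


class TestReadValidate:
    def test_round_trip(self, tmp_path):
        t = _trace([0.2095, 0.2045, 0.2046], segment=["R", "S", "S"])
        p = tmp_path / "t.csv"
        resp.write_trace(t, p)
        back = resp.read_trace(p, _meta())
        assert np.allclose(back.o2_fraction, t.o2_fraction)
        assert (back.data["segment"] == t.data["segment"]).all()
        assert (back.timestamps == t.timestamps).all()

    def test_missing_column_raises_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("timestamp,o2_fraction\n2019-06-01T10:00:00,0.2\n")
        with pytest.raises(resp.SchemaError):
            resp.read_trace(p, _meta())

    def test_out_of_range_fraction_rejected(self, tmp_path):
        t = _trace([0.2095, 0.30, 0.2046])
        p = tmp_path / "t.csv"
        resp.write_trace(t, p)
        with pytest.raises(resp.TraceDataError):
            resp.read_trace(p, _meta())

    def test_non_monotone_timestamps_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "timestamp,o2_fraction,segment\n"
            "2019-06-01T10:00:10,0.2045,S\n2019-06-01T10:00:00,0.2045,S\n"
        )
        with pytest.raises(resp.TraceDataError):
            resp.read_trace(p, _meta())

    def test_gaps_recorded_not_filled(self, tmp_path):
        idx = list(pd.date_range("2019-06-01 10:00:00", periods=6, freq="10s"))
        idx.append(pd.Timestamp("2019-06-01 10:01:50"))  # 60-s hole
        df = pd.DataFrame(
            {"timestamp": idx, "o2_fraction": [0.2045] * 7, "segment": ["S"] * 7}
        )
        p = tmp_path / "t.csv"
        t = resp.RawO2Trace(data=df, flow_lph=50.0)
        resp.write_trace(t, p)
        back = resp.read_trace(p, _meta())
        assert len(back.data) == 7  # gap not filled
        assert len(back.gaps) == 1 and back.gaps[0][1] == 60.0


class TestDriftCorrect:
    def test_linear_drift_removed_exactly(self):
        # 2-min reference / 4-min sample blocks with a pure linear ramp:
        # after correction every sample row should read the true fraction.
        rows = []
        start = pd.Timestamp("2019-06-01 10:00:00")
        true_s, fio2 = 0.2045, 0.2095
        for k in range(4000):
            t = start + pd.Timedelta(seconds=10 * k)
            cyc = (10 * k / 60.0) % 30.0
            ref = cyc >= 25.0
            drift = 5e-4 * (10 * k / 3600.0)
            rows.append((t, (fio2 if ref else true_s) + drift, "R" if ref else "S"))
        df = pd.DataFrame(rows, columns=["timestamp", "o2_fraction", "segment"])
        t = resp.RawO2Trace(data=df, flow_lph=50.0)
        out = resp.drift_correct(t, fio2=fio2)
        # interior samples (between two anchors) are restored to ~1e-5
        inner = out.data["o2_fraction"].iloc[200:-200]
        assert np.abs(inner - true_s).max() < 2e-5

    def test_idempotent(self):
        seg = ["R"] * 30 + ["S"] * 60 + ["R"] * 30
        t = _trace([0.2095] * 30 + [0.2045] * 60 + [0.2095] * 30, segment=seg)
        once = resp.drift_correct(t)
        twice = resp.drift_correct(once)
        assert twice is once

    def test_no_reference_segments_raises(self):
        t = _trace([0.2045] * 10)
        with pytest.raises(resp.TraceDataError):
            resp.drift_correct(t)

    def test_reference_rows_dropped(self):
        seg = ["R"] * 30 + ["S"] * 60 + ["R"] * 30
        t = _trace([0.2095] * 30 + [0.2045] * 60 + [0.2095] * 30, segment=seg)
        out = resp.drift_correct(t)
        assert (out.data["segment"] == resp.SAMPLE).all()
        assert len(out.data) == 60


class TestFlowEquation:
    def test_worked_example(self):
        # hand-computed: 50000·(0.2095−0.2045)/(1−0.2045·0.15) = 257.911 ml/h
        t = _trace([0.2045])
        t.drift_corrected = True
        mt = resp.compute_vo2(t, fio2=0.2095, rq=0.85)
        assert mt.data["vo2_ml_h"].iloc[0] == pytest.approx(257.9114332, abs=1e-5)

    def test_zero_depletion_gives_zero(self):
        t = _trace([0.2095])
        mt = resp.compute_vo2(t)
        assert mt.data["vo2_ml_h"].iloc[0] == 0.0

    def test_negative_rates_clipped_and_counted(self):
        t = _trace([0.2096, 0.2094])
        mt = resp.compute_vo2(t)
        assert mt.n_clipped == 1
        assert (mt.data["vo2_ml_h"] >= 0).all()

    def test_mass_specific(self):
        t = _trace([0.2045])
        mt = resp.mass_specific_mr(resp.compute_vo2(t), 50.0)
        assert mt.mr.iloc[0] == pytest.approx(257.9114332 / 50.0, abs=1e-6)

    def test_bad_mass_rejected(self):
        t = _trace([0.2045])
        with pytest.raises(ValueError):
            resp.mass_specific_mr(resp.compute_vo2(t), 0.0)


class TestPerMinute:
    def test_minute_means_and_nan_gaps(self):
        t = _trace([0.2045] * 6 + [0.2035] * 6)
        mt = resp.mass_specific_mr(resp.compute_vo2(t), 50.0)
        # punch a hole: drop the second minute entirely
        mt.data = mt.data.drop(index=range(6, 12)).reset_index(drop=True)
        extra = mt.data.iloc[-1:].copy()
        extra["timestamp"] = pd.Timestamp("2019-06-01 10:02:00")
        mt.data = pd.concat([mt.data, extra], ignore_index=True)
        pm = resp.per_minute_series(mt)
        assert len(pm) == 3
        assert np.isnan(pm.iloc[1])
        assert pm.iloc[0] == pytest.approx(257.9114332 / 50.0, abs=1e-6)
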