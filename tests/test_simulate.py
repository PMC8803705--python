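"""Synthetic-run generator: determinism, distributions, observability."""

import numpy as np
import pandas as pd
import pytest

from heterotherm import classifier as cls
from heterotherm import simulate as sim


class TestConfig:
    def test_unknown_profile_rejected(self):
        with pytest.raises(ValueError):
            sim.SimConfig(profile="desert")

    def test_full_depth_rejected(self):
        with pytest.raises(ValueError):
            sim.SimConfig(micro_depth=sim.TruncNorm(0.9, 0.05, 0.8, 1.0))


class TestEnvironment:
    def test_cave_daily_range_within_reported_bounds(self):
        env = sim.generate_environment(sim.SimConfig(profile="cave_dry", seed=0))
        assert env["t_a_c"].max() - env["t_a_c"].min() <= 0.3 + 1e-9
        assert env["t_a_c"].between(29.3, 29.6).all()

    def test_forest_diel_cycle(self):
        env = sim.generate_environment(sim.SimConfig(profile="forest_wet", seed=0))
        env["hour"] = env["timestamp"].dt.hour
        daily = env.groupby(env["timestamp"].dt.date)["t_a_c"].agg(["min", "max"])
        spans = daily["max"] - daily["min"]
        # full days approach the reported ~13.8 °C daily variation
        assert spans.max() > 10.0
        # peak in the early afternoon, trough in the early morning
        hot = env.groupby("hour")["t_a_c"].mean().idxmax()
        cold = env.groupby("hour")["t_a_c"].mean().idxmin()
        assert 12 <= hot <= 16
        assert cold in (0, 1, 2, 3, 4)

    def test_rh_anticorrelated_in_forest(self):
        env = sim.generate_environment(sim.SimConfig(profile="forest_wet", seed=0))
        assert env["t_a_c"].corr(env["rh_pct"]) < -0.8

    def test_seed_determinism(self):
        cfg = sim.SimConfig(profile="forest_wet", seed=5)
        a = sim.generate_environment(cfg)
        b = sim.generate_environment(cfg)
        pd.testing.assert_frame_equal(a, b)


class TestSchedule:
    def test_micro_durations_within_reported_range(self):
        cfg = sim.SimConfig(profile="cave_dry", seed=4, strategy=cls.MICRO_ONLY)
        truth = sim.generate_schedule(cfg)
        micro = [b for b in truth.bouts if b.bout_type == cls.MICRO]
        assert micro
        assert all(5.0 <= b.duration_min <= 36.0 for b in micro)
        assert all(0.63 <= b.depth <= 0.89 for b in micro)

    def test_extended_duration_within_reported_range(self):
        cfg = sim.SimConfig(profile="cave_wet", seed=4, strategy=cls.EXTENDED_ONLY)
        truth = sim.generate_schedule(cfg)
        ext = [b for b in truth.bouts if b.bout_type == cls.EXTENDED]
        assert ext
        assert all(1.7 * 60 <= b.duration_min <= 8.3 * 60 for b in ext)
        assert all(0.70 <= b.depth <= 0.94 for b in ext)

    def test_euthermic_strategy_has_no_bouts(self):
        cfg = sim.SimConfig(profile="cave_dry", seed=4, strategy=cls.EUTHERMIC)
        assert sim.generate_schedule(cfg).bouts == []

    def test_bouts_disjoint_with_gaps(self):
        cfg = sim.SimConfig(profile="cave_dry", seed=9,
                            strategy=cls.MICRO_PLUS_EXTENDED)
        truth = sim.generate_schedule(cfg)
        bouts = sorted(truth.bouts, key=lambda b: b.t0)
        for prev, nxt in zip(bouts, bouts[1:]):
            gap_min = (nxt.t0 - prev.t1).total_seconds() / 60.0
            assert gap_min >= 5.0 - 1e-9

    def test_no_bout_during_settling(self):
        for seed in range(5):
            cfg = sim.SimConfig(profile="cave_dry", seed=seed)
            truth = sim.generate_schedule(cfg)
            earliest = cfg.run_start + pd.Timedelta(minutes=cfg.settle_min)
            assert all(pd.Timestamp(b.t0) >= earliest for b in truth.bouts)

    def test_true_dree_matches_independent_integration(self):
        cfg = sim.SimConfig(profile="cave_dry", seed=3)
        truth = sim.generate_schedule(cfg)
        assert truth.dree_kj_g
        for day, val in truth.dree_kj_g.items():
            grid = pd.date_range(
                pd.Timestamp.combine(day, cfg.sunrise),
                pd.Timestamp.combine(day, cfg.sunset),
                freq="500ms", inclusive="left",
            )
            mr = sim.mr_waveform(cfg, truth, grid)
            ref = mr.mean() * 12.5 * 20.365 / 1000.0  # 06:00–18:30 photophase
            assert val == pytest.approx(ref, rel=1e-3)


class TestTrace:
    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        cfg = sim.SimConfig(profile="forest_wet", seed=13, run_hours=12.0)
        p1 = sim.write_run(sim.generate_run(cfg), tmp_path / "a")
        p2 = sim.write_run(sim.generate_run(cfg), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_duty_cycle_imposed(self):
        run = sim.generate_run(sim.SimConfig(profile="cave_dry", seed=2,
                                             run_hours=3.0))
        seg = run.raw.data["segment"]
        frac_ref = (seg == "R").mean()
        assert frac_ref == pytest.approx(5.0 / 60.0, abs=0.01)

    def test_micro_bouts_leave_no_tskin_signature(self):
        cfg = sim.SimConfig(profile="cave_dry", seed=6, strategy=cls.MICRO_ONLY,
                            tskin_noise_sd=0.0)
        run = sim.generate_run(cfg)
        assert np.allclose(run.tskin["t_skin_c"], cfg.tskin_eu_c)

    def test_extended_bout_tskin_direction(self):
        for profile, sign in [("cave_wet", -1.0), ("forest_wet", 1.0)]:
            cfg = sim.SimConfig(profile=profile, seed=6,
                                strategy=cls.EXTENDED_ONLY, tskin_noise_sd=0.0)
            run = sim.generate_run(cfg)
            dev = run.tskin["t_skin_c"] - cfg.tskin_eu_c
            peak = dev.iloc[np.argmax(np.abs(dev.to_numpy()))]
            assert np.sign(peak) == sign and abs(peak) > 1.5

    def test_detectable_bouts_annotations(self):
        cfg = sim.SimConfig(profile="cave_dry", seed=0)
        run = sim.generate_run(cfg)
        det = sim.detectable_bouts(run.truth, cfg)
        assert len(det) == len(run.truth.bouts)
        assert (det.loc[det["detectable"], "observed_span_min"] >= 5.0).all()
        # an edge hidden inside a reference window is never "edges_sampled"
        assert set(det.columns) >= {"detectable", "edges_sampled",
                                    "observed_span_min"}


class TestCohort:
    def test_strategies_cycled_deterministically(self):
        runs = sim.generate_cohort(4, "cave_dry", seed=1, run_hours=12.0,
                                   strategies=[cls.MICRO_ONLY, cls.EUTHERMIC])
        assert [r.config.strategy for r in runs] == [
            cls.MICRO_ONLY, cls.EUTHERMIC, cls.MICRO_ONLY, cls.EUTHERMIC]
        assert len({r.config.seed for r in runs}) == 4
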