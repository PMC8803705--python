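"""Synthetic respirometry runs with known ground truth.

The study system is a large tropical bat measured in a 2-L chamber under
open-flow (pull-mode) respirometry for ~45 h, either inside a thermally
stable cave (dry or wet season) or in an exposed forest roost with a strong
diel temperature cycle.  The generator reproduces the measurement chain end
to end: a state schedule (rest, nocturnal activity, micro/extended torpor
bouts with exponential entry/arousal ramps), the implied mass-specific MR
waveform with a mild RMR–Tₐ dependence below the lower critical temperature,
inversion through the flow equation to excurrent O2 fractions, linear sensor
drift, Gaussian sensor noise and 55-min-sample / 5-min-reference cycling,
plus a 5-min skin-temperature trace whose excursions accompany extended
bouts only (a drop in the cave, a rise in the hot forest roost).

Everything downstream (drift correction, V̇O2, classification, TMR, DREE)
can therefore be validated against exact ground truth.  All randomness flows
through a single mandatory seed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import classifier as cls
from .energetics import oxycal_equivalent
from .respirometry import REFERENCE, SAMPLE, RawO2Trace, RunMetadata

PROFILES = {
    # Tₐ: mean, sinusoid amplitude (half the daily range), noise SD, clip range.
    # RHₐ: mean, anti-correlation slope vs Tₐ, clip range.
    # ΔT_skin during extended torpor: negative (drop) in the cave roost,
    # positive (rise) in the hot forest roost.
    "cave_dry": dict(
        ta_mean=29.4, ta_amplitude=0.05, ta_noise=0.03, ta_clip=(29.3, 29.6),
        rh_mean=98.8, rh_slope=-2.0, rh_clip=(96.4, 100.5),
        ext_dtskin_c=-2.9, active_night=False, start_hour=10,
    ),
    "cave_wet": dict(
        ta_mean=30.6, ta_amplitude=0.08, ta_noise=0.03, ta_clip=(30.3, 30.7),
        rh_mean=95.2, rh_slope=-2.0, rh_clip=(93.8, 96.6),
        ext_dtskin_c=-2.9, active_night=False, start_hour=21,
    ),
    "forest_wet": dict(
        ta_mean=27.5, ta_amplitude=6.9, ta_noise=0.3, ta_clip=(21.2, 41.7),
        rh_mean=80.1, rh_slope=-3.5, rh_clip=(29.0, 101.2),
        ext_dtskin_c=+1.9, active_night=True, start_hour=21,
    ),
}

STRATEGIES = (cls.EUTHERMIC, cls.MICRO_ONLY, cls.MICRO_PLUS_EXTENDED, cls.EXTENDED_ONLY)
#: Observed animal-day counts per strategy (euthermic, micro-only,
#: micro+extended, extended-only) used as default sampling weights.
STRATEGY_WEIGHTS = (5, 42, 35, 10)


@dataclass(frozen=True)
class TruncNorm:
    """Mean/SD/range of a truncated-normal draw (the reported summaries)."""

    mean: float
    sd: float
    lo: float
    hi: float

    def rvs(self, rng: np.random.Generator, size=None):
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return sps.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                 size=size, random_state=rng)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated run.

    Defaults encode the field protocol: 10-s O2 sampling in 55/5
    sample/reference cycles at 50 L h⁻¹, a ~45-h run starting at the site's
    usual handling time, RQ 0.85, a ~50 g animal with a euthermic floor of
    1.0 ml O2 g⁻¹ h⁻¹ inside the thermoneutral zone, micro bouts of
    17 ± 8 min (5–36), extended bouts of 4.9 ± 1 h (1.7–8.3), metabolic
    depressions of ~76 % (63–89 %) for micro and ~84 % for extended torpor.
    """

    profile: str = "cave_dry"
    seed: int = 0
    run_hours: float = 45.0
    start: dt.datetime | None = None  # profile default when None
    cadence_s: float = 10.0
    sample_min: float = 55.0
    ref_min: float = 5.0
    flow_lph: float = 50.0
    fio2: float = 0.2095
    rq: float = 0.85
    bm_g: float = 50.0
    rmr_ml_g_h: float = 1.0
    t_lc_c: float = 32.0
    rmr_ta_slope: float | None = None  # per °C below t_lc; profile default
    micro_depth: TruncNorm = TruncNorm(0.76, 0.06, 0.63, 0.89)
    ext_depth: TruncNorm = TruncNorm(0.84, 0.05, 0.70, 0.94)
    micro_dur_min: TruncNorm = TruncNorm(17.0, 8.0, 5.0, 36.0)
    ext_dur_h: TruncNorm = TruncNorm(4.9, 58.0 / 60.0, 1.7, 8.3)
    n_micro: TruncNorm = TruncNorm(12.0, 6.9, 1.0, 24.0)
    min_gap_min: float = 5.0
    entry_tau_s: float = 10.0
    arousal_tau_s: float = 10.0
    noise_sd: float = 1e-5
    drift_per_h: float = 2e-5
    sunrise: dt.time = dt.time(6, 0)
    sunset: dt.time = dt.time(18, 30)
    tskin_eu_c: float = 36.5
    tskin_noise_sd: float = 0.2
    tskin_tau_min: float = 15.0
    active_mr_factor: float = 2.0
    settle_min: float = 45.0  # no torpor right after handling/chamber entry
    strategy: str | None = None  # fixed strategy, else drawn per day

    def __post_init__(self):
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        for tn in (self.micro_depth, self.ext_depth):
            if tn.hi >= 1.0:
                raise ValueError("torpor depth must stay below 100%")

    @property
    def run_start(self) -> dt.datetime:
        if self.start is not None:
            return self.start
        base = dt.date(2019, 6, 1) if self.profile == "cave_dry" else dt.date(2019, 2, 1)
        return dt.datetime.combine(base, dt.time(PROFILES[self.profile]["start_hour"], 0))

    @property
    def run_end(self) -> dt.datetime:
        return self.run_start + dt.timedelta(hours=self.run_hours)

    @property
    def ta_slope(self) -> float:
        if self.rmr_ta_slope is not None:
            return self.rmr_ta_slope
        # the RMR–Tₐ slope is much shallower in the forest roost
        return 0.005 if self.profile == "forest_wet" else 0.02


@dataclass
class TrueBout:
    day: dt.date
    bout_type: str
    t0: dt.datetime
    t1: dt.datetime
    depth: float

    @property
    def duration_min(self) -> float:
        return (self.t1 - self.t0).total_seconds() / 60.0


@dataclass
class GroundTruth:
    """Everything the pipeline is later asked to recover."""

    bouts: list[TrueBout]
    strategies: dict[dt.date, str]  # full-coverage rest days only
    active_blocks: list[tuple[dt.datetime, dt.datetime]]
    dree_kj_g: dict[dt.date, float] = field(default_factory=dict)
    rmr_baseline_ml_g_h: float = np.nan

    def bout_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "date": b.day, "bout_type": b.bout_type, "t0": b.t0,
                    "t1": b.t1, "depth": b.depth, "duration_min": b.duration_min,
                }
                for b in self.bouts
            ]
        )


def _seconds(ts: pd.DatetimeIndex | pd.Series, origin: dt.datetime) -> np.ndarray:
    return (pd.DatetimeIndex(ts) - pd.Timestamp(origin)).total_seconds().to_numpy()


def generate_environment(cfg: SimConfig, freq: str = "5min") -> pd.DataFrame:
    """Ambient Tₐ/RHₐ logger trace for the run.

    Cave profiles are near-constant; the forest follows a sinusoid peaking
    in the early afternoon (14:00) with the observed daily amplitude.  RH is
    anti-correlated with Tₐ.  Values are clipped to the observed ranges.
    """
    p = PROFILES[cfg.profile]
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    idx = pd.date_range(cfg.run_start, cfg.run_end, freq=freq, inclusive="left")
    hours = idx.hour + idx.minute / 60.0
    diel = np.cos(2 * np.pi * (hours - 14.0) / 24.0)  # peak 14:00, trough 02:00
    ta = p["ta_mean"] + p["ta_amplitude"] * diel + rng.normal(0, p["ta_noise"], len(idx))
    ta = np.clip(ta, *p["ta_clip"])
    rh = p["rh_mean"] + p["rh_slope"] * (ta - p["ta_mean"]) + rng.normal(0, 0.3, len(idx))
    rh = np.clip(rh, *p["rh_clip"])
    return pd.DataFrame({"timestamp": idx, "t_a_c": ta, "rh_pct": rh})


def ambient_temperature(cfg: SimConfig, times: pd.DatetimeIndex) -> np.ndarray:
    """Noiseless Tₐ at arbitrary times (the waveform the MR model sees)."""
    p = PROFILES[cfg.profile]
    hours = np.asarray(times.hour + times.minute / 60.0 + times.second / 3600.0, dtype=float)
    diel = np.cos(2 * np.pi * (hours - 14.0) / 24.0)
    return np.clip(p["ta_mean"] + p["ta_amplitude"] * diel, *p["ta_clip"])


def _rest_days(cfg: SimConfig) -> list[tuple[dt.date, dt.datetime, dt.datetime, bool]]:
    """(day, bout-window start, bout-window end, full-coverage) per day."""
    out = []
    day = cfg.run_start.date()
    while day <= cfg.run_end.date():
        rise = dt.datetime.combine(day, cfg.sunrise)
        sset = dt.datetime.combine(day, cfg.sunset) - dt.timedelta(minutes=30)
        lo = max(rise, cfg.run_start + dt.timedelta(minutes=cfg.settle_min))
        hi = min(sset, cfg.run_end)
        if hi - lo >= dt.timedelta(hours=2):
            full = lo == rise and hi == sset
            out.append((day, lo, hi, full))
        day += dt.timedelta(days=1)
    return out


def _place_bouts(
    rng: np.random.Generator,
    lo: dt.datetime,
    hi: dt.datetime,
    durations_min: list[float],
    anchored: list[dt.datetime | None],
    min_gap_min: float,
    max_tries: int = 100,
) -> list[tuple[int, dt.datetime, dt.datetime]]:
    """Draw non-overlapping bout intervals within [lo, hi].

    ``anchored`` supplies a preferred start per bout (None for uniform).
    Bouts are placed sequentially with at least ``min_gap_min`` between
    them; anchored bouts go first (and must fit — ``RuntimeError`` after
    ``max_tries``), unanchored bouts that cannot be squeezed in after
    ``max_tries`` draws are dropped.  Returns (request index, start, end)
    tuples, sorted by start.
    """
    span_min = (hi - lo).total_seconds() / 60.0
    gap = dt.timedelta(minutes=min_gap_min)
    placed: list[tuple[int, dt.datetime, dt.datetime]] = []

    def overlaps(start, end):
        return any(start < e + gap and end + gap > s for _, s, e in placed)

    order = sorted(range(len(durations_min)), key=lambda i: anchored[i] is None)
    for i in order:
        dur = durations_min[i]
        if dur > span_min:
            if anchored[i] is not None:
                raise RuntimeError(f"a {dur:.0f}-min bout cannot fit a {span_min:.0f}-min window")
            continue
        success = False
        for _ in range(max_tries):
            if anchored[i] is not None:
                start = min(max(anchored[i], lo), hi - dt.timedelta(minutes=dur))
                anchored[i] = None if overlaps(start, start + dt.timedelta(minutes=dur)) else anchored[i]
            else:
                start = lo + dt.timedelta(minutes=float(rng.uniform(0, span_min - dur)))
            end = start + dt.timedelta(minutes=dur)
            if not overlaps(start, end):
                placed.append((i, start, end))
                success = True
                break
        if not success and anchored[i] is not None:
            raise RuntimeError(
                f"could not place an anchored {dur:.0f}-min bout in a "
                f"{span_min:.0f}-min window after {max_tries} tries"
            )
    return sorted(placed, key=lambda t: t[1])


def generate_schedule(cfg: SimConfig) -> GroundTruth:
    """Draw the per-day strategy and the daytime-anchored bout schedule.

    Strategies are drawn with the observed animal-day mix (5 euthermic : 42
    micro-only : 35 micro+extended : 10 extended-only) unless fixed in the
    config.  Extended bouts enter mid-morning (around 10:00); micro bouts
    are scattered uniformly over the rest window with a minimum 5-min gap.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    weights = np.asarray(STRATEGY_WEIGHTS, dtype=float)
    weights /= weights.sum()
    bouts: list[TrueBout] = []
    strategies: dict[dt.date, str] = {}
    for day, lo, hi, full in _rest_days(cfg):
        strat = cfg.strategy or str(rng.choice(STRATEGIES, p=weights))
        if full:
            strategies[day] = strat
        durations: list[float] = []
        kinds: list[str] = []
        anchors: list[dt.datetime | None] = []
        if strat in (cls.MICRO_PLUS_EXTENDED, cls.EXTENDED_ONLY):
            # shorter extended bout when combined with micro bouts
            edur = float(cfg.ext_dur_h.rvs(rng)) * 60.0
            if strat == cls.MICRO_PLUS_EXTENDED:
                edur = min(edur, 0.55 * (hi - lo).total_seconds() / 60.0)
            span = (hi - lo).total_seconds() / 60.0
            latest = span - edur
            pref = (dt.datetime.combine(day, dt.time(10, 0)) - lo).total_seconds() / 60.0
            start_min = float(np.clip(rng.normal(pref, 40.0), 0.0, max(0.0, latest)))
            anchors.append(lo + dt.timedelta(minutes=start_min))
            durations.append(edur)
            kinds.append(cls.EXTENDED)
        if strat in (cls.MICRO_ONLY, cls.MICRO_PLUS_EXTENDED):
            span_min = (hi - lo).total_seconds() / 60.0
            n = int(round(float(cfg.n_micro.rvs(rng)) * min(1.0, span_min / 720.0)))
            if strat == cls.MICRO_PLUS_EXTENDED:
                n = max(1, n // 3)
            n = max(1, n)
            for _ in range(n):
                durations.append(float(cfg.micro_dur_min.rvs(rng)))
                kinds.append(cls.MICRO)
                anchors.append(None)
        if not durations:
            continue
        for i, start, end in _place_bouts(rng, lo, hi, durations, anchors, cfg.min_gap_min):
            kind = kinds[i]
            depth_dist = cfg.micro_depth if kind == cls.MICRO else cfg.ext_depth
            bouts.append(
                TrueBout(
                    day=day, bout_type=kind, t0=start, t1=end,
                    depth=float(depth_dist.rvs(rng)),
                )
            )
    active = []
    if PROFILES[cfg.profile]["active_night"]:
        day = cfg.run_start.date() - dt.timedelta(days=1)
        while day <= cfg.run_end.date():
            a0 = dt.datetime.combine(day, cfg.sunset) + dt.timedelta(minutes=30)
            a1 = a0 + dt.timedelta(hours=5)
            a0, a1 = max(a0, cfg.run_start), min(a1, cfg.run_end)
            if a1 > a0:
                active.append((a0, a1))
            day += dt.timedelta(days=1)
    bouts.sort(key=lambda b: b.t0)
    truth = GroundTruth(bouts=bouts, strategies=strategies, active_blocks=active)
    _attach_truth_energetics(cfg, truth)
    return truth


def mr_waveform(cfg: SimConfig, truth: GroundTruth, times: pd.DatetimeIndex) -> np.ndarray:
    """Noiseless mass-specific MR (ml O2 g⁻¹ h⁻¹) at the given times.

    Base level: the euthermic floor plus a linear increase below the lower
    critical temperature.  Torpor bouts depress the base by their depth with
    exponential entry ramps and post-bout arousal recovery; nocturnal
    activity multiplies the base.
    """
    ta = ambient_temperature(cfg, times)
    base = cfg.rmr_ml_g_h + cfg.ta_slope * np.maximum(0.0, cfg.t_lc_c - ta)
    t_s = _seconds(times, cfg.run_start)
    depression = np.zeros(len(times))
    for b in truth.bouts:
        b0 = (b.t0 - cfg.run_start).total_seconds()
        b1 = (b.t1 - cfg.run_start).total_seconds()
        inside = (t_s >= b0) & (t_s < b1)
        after = t_s >= b1
        d_in = b.depth * (1.0 - np.exp(-(t_s[inside] - b0) / cfg.entry_tau_s))
        d_after = b.depth * np.exp(-(t_s[after] - b1) / cfg.arousal_tau_s)
        depression[inside] = np.maximum(depression[inside], d_in)
        depression[after] = np.maximum(depression[after], d_after)
    mr = base * (1.0 - depression)
    for a0, a1 in truth.active_blocks:
        mask = (t_s >= (a0 - cfg.run_start).total_seconds()) & (
            t_s < (a1 - cfg.run_start).total_seconds()
        )
        # activity never overrides a torpor depression
        mr[mask] = np.where(
            depression[mask] > 0.01, mr[mask], base[mask] * cfg.active_mr_factor
        )
    return mr


def _attach_truth_energetics(cfg: SimConfig, truth: GroundTruth) -> None:
    """True DREE (sunrise–sunset integral of the noiseless waveform) per
    fully covered day, and the mean daytime euthermic base level."""
    oxycal = oxycal_equivalent(cfg.rq)
    for day, strat in truth.strategies.items():
        rise = dt.datetime.combine(day, cfg.sunrise)
        sset = dt.datetime.combine(day, cfg.sunset)
        if rise < cfg.run_start or sset > cfg.run_end:
            continue
        grid = pd.date_range(rise, sset, freq="1s", inclusive="left")
        mr = mr_waveform(cfg, truth, grid)
        ml_g = float(mr.sum()) / 3600.0  # ml O2 per g
        truth.dree_kj_g[day] = ml_g * oxycal / 1000.0
    # run-mean euthermic daytime base level (for recovery checks)
    days = _rest_days(cfg)
    if days:
        vals = []
        for day, lo, hi, _ in days:
            grid = pd.date_range(lo, hi, freq="60s", inclusive="left")
            ta = ambient_temperature(cfg, grid)
            vals.append(cfg.rmr_ml_g_h + cfg.ta_slope * np.maximum(0.0, cfg.t_lc_c - ta))
        truth.rmr_baseline_ml_g_h = float(np.concatenate(vals).mean())


def sample_times(cfg: SimConfig) -> tuple[pd.DatetimeIndex, np.ndarray]:
    """The run's 10-s grid and a mask of reference (blind) rows."""
    idx = pd.date_range(cfg.run_start, cfg.run_end, freq=f"{int(cfg.cadence_s)}s",
                        inclusive="left")
    t_s = _seconds(idx, cfg.run_start)
    cycle_min = (t_s / 60.0) % (cfg.sample_min + cfg.ref_min)
    return idx, cycle_min >= cfg.sample_min


def detectable_bouts(
    truth: GroundTruth, cfg: SimConfig, min_bout_min: float = 5.0,
    edge_margin_s: float = 30.0,
) -> pd.DataFrame:
    """Ground-truth bouts annotated with their observability under the
    55/5 sample/reference duty cycle.

    A bout is ``detectable`` when the wall-clock span of chamber-air samples
    falling inside it reaches ``min_bout_min`` (a bout hiding mostly inside
    a reference window cannot be seen by any method).  ``edges_sampled``
    marks bouts whose entry and exit both occur at least ``edge_margin_s``
    of sampled time away from a reference window, i.e. whose duration is
    measurable to within the threshold-crossing lag.
    """
    idx, is_ref = sample_times(cfg)
    stimes = idx[~is_ref]
    rows = []
    for b in truth.bouts:
        # exact sub-threshold interval of the noiseless waveform: the
        # exponential ramps cross the 50% threshold with a small lag
        lag_in = cfg.entry_tau_s * np.log(b.depth / (b.depth - 0.5))
        lag_out = cfg.arousal_tau_s * np.log(b.depth / 0.5)
        tin = pd.Timestamp(b.t0) + pd.Timedelta(seconds=lag_in)
        tout = pd.Timestamp(b.t1) + pd.Timedelta(seconds=lag_out)
        inside = stimes[(stimes >= tin) & (stimes <= tout)]
        if len(inside):
            span = (inside[-1] - inside[0]).total_seconds() / 60.0 + cfg.cadence_s / 60.0
        else:
            span = 0.0
        def _edge_clear(t: dt.datetime) -> bool:
            w = stimes[(stimes >= pd.Timestamp(t) - pd.Timedelta(seconds=edge_margin_s))
                       & (stimes <= pd.Timestamp(t) + pd.Timedelta(seconds=edge_margin_s))]
            return len(w) >= int(2 * edge_margin_s / cfg.cadence_s)
        rows.append(
            {
                "date": b.day, "bout_type": b.bout_type, "t0": b.t0, "t1": b.t1,
                "depth": b.depth, "duration_min": b.duration_min,
                "observed_span_min": span,
                "detectable": span >= min_bout_min,
                "edges_sampled": _edge_clear(b.t0) and _edge_clear(b.t1),
            }
        )
    return pd.DataFrame(rows)


def generate_trace(
    truth: GroundTruth, cfg: SimConfig
) -> tuple[RawO2Trace, pd.DataFrame]:
    """Raw O2 trace (with drift, noise, 55/5 cycling) and T_skin trace.

    The MR waveform is inverted through the flow equation to excurrent O2
    fractions; reference rows read incurrent air.  Both see the same linear
    sensor drift and Gaussian noise.  T_skin sits at the euthermic level
    with exponential excursions during extended (not micro) bouts.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    idx = pd.date_range(cfg.run_start, cfg.run_end, freq=f"{int(cfg.cadence_s)}s",
                        inclusive="left")
    t_s = _seconds(idx, cfg.run_start)
    mr = mr_waveform(cfg, truth, idx)
    vo2 = mr * cfg.bm_g
    fr_ml = cfg.flow_lph * 1000.0
    feo2 = (fr_ml * cfg.fio2 - vo2) / (fr_ml - vo2 * (1.0 - cfg.rq))
    cycle_min = (t_s / 60.0) % (cfg.sample_min + cfg.ref_min)
    is_ref = cycle_min >= cfg.sample_min
    drift = cfg.drift_per_h * t_s / 3600.0
    o2 = np.where(is_ref, cfg.fio2, feo2) + drift + rng.normal(0, cfg.noise_sd, len(idx))
    raw = RawO2Trace(
        data=pd.DataFrame(
            {
                "timestamp": idx,
                "o2_fraction": o2,
                "segment": np.where(is_ref, REFERENCE, SAMPLE),
            }
        ),
        flow_lph=cfg.flow_lph,
        animal_id=f"sim-{cfg.profile}-{cfg.seed}",
    )

    sidx = pd.date_range(cfg.run_start, cfg.run_end, freq="5min", inclusive="left")
    st = _seconds(sidx, cfg.run_start)
    excursion = np.zeros(len(sidx))
    dt_ext = PROFILES[cfg.profile]["ext_dtskin_c"]
    tau = cfg.tskin_tau_min * 60.0
    for b in truth.bouts:
        if b.bout_type == cls.MICRO:
            continue  # micro bouts leave no T_skin signature
        b0 = (b.t0 - cfg.run_start).total_seconds()
        b1 = (b.t1 - cfg.run_start).total_seconds()
        inside = (st >= b0) & (st < b1)
        after = st >= b1
        excursion[inside] = dt_ext * (1.0 - np.exp(-(st[inside] - b0) / tau))
        decay = dt_ext * np.exp(-(st[after] - b1) / tau)
        excursion[after] = np.where(np.abs(decay) > np.abs(excursion[after]), decay, excursion[after])
    tskin = cfg.tskin_eu_c + excursion + rng.normal(0, cfg.tskin_noise_sd, len(sidx))
    tskin_df = pd.DataFrame({"timestamp": sidx, "t_skin_c": tskin})
    return raw, tskin_df


@dataclass
class SimRun:
    """One complete simulated run plus its ground truth."""

    raw: RawO2Trace
    tskin: pd.DataFrame
    environment: pd.DataFrame
    truth: GroundTruth
    metadata: RunMetadata
    config: SimConfig

    def resting_windows(self) -> list[cls.RestingWindow]:
        return cls.resting_windows_for_span(
            self.config.run_start,
            self.config.run_end,
            sunrise_override=self.config.sunrise,
            sunset_override=self.config.sunset,
        )


def generate_run(cfg: SimConfig) -> SimRun:
    """Generate a full run: schedule, environment, O2 and T_skin traces."""
    truth = generate_schedule(cfg)
    raw, tskin = generate_trace(truth, cfg)
    env = generate_environment(cfg)
    meta = RunMetadata(
        flow_lph=cfg.flow_lph,
        bm_pre_g=cfg.bm_g,
        bm_post_g=cfg.bm_g,
        animal_id=raw.animal_id,
        site_season=cfg.profile,
        fio2=cfg.fio2,
        rq=cfg.rq,
    )
    return SimRun(raw=raw, tskin=tskin, environment=env, truth=truth,
                  metadata=meta, config=cfg)


def generate_cohort(
    n_animals: int,
    profile: str,
    seed: int,
    strategies: list[str] | None = None,
    **cfg_overrides,
) -> list[SimRun]:
    """A cohort of runs with deterministic per-animal strategy assignment.

    When ``strategies`` is given it is cycled across animals so the cohort's
    strategy mix is exactly as configured; otherwise each animal-day draws
    from the default mix.
    """
    runs = []
    for i in range(n_animals):
        strat = strategies[i % len(strategies)] if strategies else None
        cfg = SimConfig(profile=profile, seed=seed * 1009 + i, strategy=strat,
                        **cfg_overrides)
        runs.append(generate_run(cfg))
    return runs


def write_run(run: SimRun, out_dir: str | Path) -> dict[str, Path]:
    """Write trace/environment/T_skin CSVs and the ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trace": out / "trace.csv",
        "environment": out / "environment.csv",
        "tskin": out / "tskin.csv",
        "truth": out / "truth.json",
        "metadata": out / "metadata.yaml",
    }
    from .respirometry import write_trace

    write_trace(run.raw, paths["trace"])
    run.environment.to_csv(paths["environment"], index=False, float_format="%.3f")
    run.tskin.to_csv(paths["tskin"], index=False, float_format="%.3f")
    truth = {
        "strategies": {d.isoformat(): s for d, s in run.truth.strategies.items()},
        "dree_kj_g": {d.isoformat(): v for d, v in run.truth.dree_kj_g.items()},
        "rmr_baseline_ml_g_h": run.truth.rmr_baseline_ml_g_h,
        "bouts": [
            {
                "date": b.day.isoformat(), "bout_type": b.bout_type,
                "t0": b.t0.isoformat(), "t1": b.t1.isoformat(),
                "depth": b.depth, "duration_min": b.duration_min,
            }
            for b in run.truth.bouts
        ],
    }
    paths["truth"].write_text(json.dumps(truth, indent=2))
    meta = dataclasses.asdict(run.metadata)
    import yaml

    paths["metadata"].write_text(yaml.safe_dump(meta))
    return paths
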