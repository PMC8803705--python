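"""Physiological-state segmentation of metabolic-rate traces.

A run is segmented into rest, torpor (micro / extended / multi-day), entry
and arousal transitions, nocturnal activity and excluded spans.  Torpor is a
drop of at least 50 % below the resting metabolic rate (RMR) baseline, which
is itself estimated from the lowest 50 % of resting-phase values per clock
hour (resting phase: sunrise to 30 min before sunset).  Torpid metabolic
rate (TMR) keeps the lowest 70 % of in-bout values per hour.  Because the
baseline needs euthermic samples and torpor detection needs the baseline,
the two are solved by fixed-point iteration: the baseline is re-estimated on
non-torpid samples until the torpid mask stabilises (the baseline can only
rise as torpid samples are excluded, so the iteration converges).

Bout taxonomy: bouts shorter than 5 min are discarded as noise, shorter than
60 min are micro-torpor, up to 24 h extended torpor, and beyond 24 h
multi-day torpor.  When a skin-temperature trace is available, extended
bouts are corroborated by an absolute skin-temperature deviation of at least
1.5 °C from the euthermic mean (sign-agnostic: animals in hot exposed roosts
may let T_skin rise during torpor rather than fall).
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import solar

# Per-sample state labels (a partition of every run).
REST = "REST"
MICRO_TORPOR = "MICRO_TORPOR"
EXTENDED_TORPOR = "EXTENDED_TORPOR"
MULTIDAY_TORPOR = "MULTIDAY_TORPOR"
ENTRY = "ENTRY"
AROUSAL = "AROUSAL"
ACTIVE = "ACTIVE"
EXCLUDED_FEEDING = "EXCLUDED_FEEDING"
EXCLUDED_STRESS = "EXCLUDED_STRESS"

# Bout types.
MICRO = "MICRO"
EXTENDED = "EXTENDED"
MULTIDAY = "MULTIDAY"

# Daily strategies.
EUTHERMIC = "EUTHERMIC"
MICRO_ONLY = "MICRO_ONLY"
MICRO_PLUS_EXTENDED = "MICRO_PLUS_EXTENDED"
EXTENDED_ONLY = "EXTENDED_ONLY"


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable thresholds of the state classifier.

    torpor_fraction
        A sample is torpid when MR ≤ this fraction of the RMR baseline
        (inclusive).
    micro_max_min / multiday_min_h
        Duration boundaries between micro, extended and multi-day bouts.
        Observed micro bouts top out around 36 min and extended bouts start
        near 1.7 h; 60 min splits the unobserved gap.
    min_bout_min
        Sub-threshold runs shorter than this are treated as noise.
    merge_gap_samples
        Torpid runs separated by at most this many supra-threshold samples
        are merged into one bout.
    tskin_delta_c
        Minimum |ΔT_skin| for an extended bout to count as T_skin-confirmed.
    slope_fraction_per_min
        Entry/arousal transition threshold: 1-min smoothed |dMR/dt| above
        this fraction of the baseline per minute.
    rmr_min_hour_samples
        Hours retaining fewer filtered samples than this are skipped when
        building the RMR baseline.
    hour_matched_baseline
        If True, torpor detection compares each sample to its own hour's
        filtered RMR (falling back to the run baseline); default is the
        single run-level baseline.
    """

    torpor_fraction: float = 0.5
    micro_max_min: float = 60.0
    multiday_min_h: float = 24.0
    min_bout_min: float = 5.0
    merge_gap_samples: int = 2
    tskin_delta_c: float = 1.5
    slope_fraction_per_min: float = 0.25
    rmr_quantile: float = 0.5
    tmr_quantile: float = 0.7
    rmr_min_hour_samples: int = 6
    hour_matched_baseline: bool = False
    stress_window_min: float = 30.0
    feeding_exclusion_h: float = 3.0
    max_baseline_iter: int = 25


@dataclass(frozen=True)
class RestingWindow:
    """One day's rest-phase analysis window: sunrise to sunset − 30 min."""

    date: dt.date
    start: dt.datetime
    end: dt.datetime

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("resting window start must precede end")

    def contains(self, timestamps: pd.Series) -> np.ndarray:
        return (
            (timestamps >= pd.Timestamp(self.start))
            & (timestamps < pd.Timestamp(self.end))
        ).to_numpy()


def resting_window(
    date: dt.date,
    latitude: float | None = None,
    longitude: float | None = None,
    utc_offset_hours: float = 0.0,
    sunrise_override: dt.time | None = None,
    sunset_override: dt.time | None = None,
    sunset_margin_min: float = 30.0,
) -> RestingWindow:
    """The rest-phase window for one day.

    Solar times come from the NOAA geometry at the site coordinates unless
    explicit overrides are given.
    """
    if sunrise_override is not None and sunset_override is not None:
        rise = dt.datetime.combine(date, sunrise_override)
        sset = dt.datetime.combine(date, sunset_override)
    elif latitude is not None and longitude is not None:
        rise, sset = solar.sunrise_sunset_local(date, latitude, longitude, utc_offset_hours)
    else:
        raise ValueError("need coordinates or explicit sunrise/sunset overrides")
    return RestingWindow(date=date, start=rise, end=sset - dt.timedelta(minutes=sunset_margin_min))


def resting_windows_for_span(
    start: dt.datetime, end: dt.datetime, **window_kwargs
) -> list[RestingWindow]:
    """Resting windows for every calendar day a time span touches."""
    out = []
    day = start.date()
    while day <= end.date():
        out.append(resting_window(day, **window_kwargs))
        day += dt.timedelta(days=1)
    return out


def apply_exclusions(
    timestamps: pd.Series,
    feeding_times: Sequence[dt.datetime] = (),
    config: ClassifierConfig = ClassifierConfig(),
    run_start: dt.datetime | None = None,
) -> pd.DataFrame:
    """Masks for samples excluded from all analyses.

    The 3 h after each feeding event are dropped (overlapping windows simply
    union), as is a configurable settling window at the start of the run
    while the animal may still be stressed from handling.
    """
    ts = pd.to_datetime(timestamps)
    feeding = np.zeros(len(ts), dtype=bool)
    for f in feeding_times:
        f = pd.Timestamp(f)
        feeding |= ((ts >= f) & (ts < f + pd.Timedelta(hours=config.feeding_exclusion_h))).to_numpy()
    stress = np.zeros(len(ts), dtype=bool)
    if config.stress_window_min > 0 and len(ts):
        t0 = pd.Timestamp(run_start) if run_start is not None else ts.iloc[0]
        stress = (ts < t0 + pd.Timedelta(minutes=config.stress_window_min)).to_numpy()
    stress &= ~feeding  # feeding exclusion takes precedence in the partition
    return pd.DataFrame({"excluded_feeding": feeding, "excluded_stress": stress})


def lowest_fraction_mask(values: np.ndarray, hours: np.ndarray, frac: float,
                         min_retained: int = 0) -> np.ndarray:
    """Per clock hour, mark the floor(frac·n) lowest values.

    Ties are broken by keeping earlier samples (stable sort).  Hours where
    fewer than ``min_retained`` values survive are dropped entirely (with a
    warning); with ``min_retained = 0`` at least one value is kept per hour.
    """
    keep = np.zeros(len(values), dtype=bool)
    for h in np.unique(hours):
        idx = np.flatnonzero(hours == h)
        k = int(np.floor(frac * len(idx)))
        if min_retained == 0:
            k = max(k, 1)
        if k < min_retained:
            warnings.warn(
                f"hour {h}: only {k} filtered samples (< {min_retained}); hour skipped",
                stacklevel=2,
            )
            continue
        order = np.argsort(values[idx], kind="stable")
        keep[idx[order[:k]]] = True
    return keep


@dataclass
class RmrBaseline:
    """Run-level RMR baseline plus the hourly filtered means behind it."""

    value: float
    hourly: pd.Series  # indexed by hour start
    retained_mask: np.ndarray


def extract_rmr(
    mr_df: pd.DataFrame,
    windows: Sequence[RestingWindow],
    excluded: np.ndarray | None = None,
    torpid: np.ndarray | None = None,
    config: ClassifierConfig = ClassifierConfig(),
) -> RmrBaseline:
    """RMR baseline from the lowest 50 % of resting-phase values per hour.

    Non-torpid, non-excluded samples inside the resting window(s) are
    grouped by clock hour; within each hour the lowest half (floor rule) is
    retained, hours with fewer than ``rmr_min_hour_samples`` retained values
    are skipped, and the run baseline is the mean of all retained values.
    """
    ts = mr_df["timestamp"]
    mask = np.zeros(len(mr_df), dtype=bool)
    for w in windows:
        mask |= w.contains(ts)
    if excluded is not None:
        mask &= ~excluded
    if torpid is not None:
        mask &= ~torpid
    sub = mr_df[mask]
    if sub.empty:
        raise ValueError("no resting-phase samples available for the RMR baseline")
    values = sub["mr_ml_g_h"].to_numpy()
    hours = sub["timestamp"].dt.floor("h").to_numpy()
    keep = lowest_fraction_mask(
        values, hours, config.rmr_quantile, min_retained=config.rmr_min_hour_samples
    )
    if not keep.any():
        raise ValueError("every resting-phase hour was skipped; trace too sparse")
    retained = values[keep]
    hourly = (
        pd.Series(retained, index=pd.DatetimeIndex(hours[keep], name="hour"))
        .groupby(level=0)
        .mean()
    )
    full_mask = np.zeros(len(mr_df), dtype=bool)
    full_mask[np.flatnonzero(mask)[keep]] = True
    return RmrBaseline(value=float(retained.mean()), hourly=hourly, retained_mask=full_mask)


def detect_torpor(
    mr: np.ndarray | pd.Series,
    baseline: float | np.ndarray,
    fraction: float = 0.5,
) -> np.ndarray:
    """Torpid-candidate mask: MR at or below ``fraction`` × baseline.

    ``baseline`` may be a scalar (run-level reference) or a per-sample array
    (hour-matched reference); the threshold is inclusive.
    """
    return np.asarray(mr, dtype=float) <= fraction * np.asarray(baseline, dtype=float)


def _per_sample_baseline(
    baseline: RmrBaseline, timestamps: pd.Series, config: ClassifierConfig
) -> float | np.ndarray:
    """Run-level baseline, or each sample's own hour's filtered RMR when
    ``hour_matched_baseline`` is set (hours without a value fall back to the
    run level)."""
    if not config.hour_matched_baseline:
        return baseline.value
    hours = pd.DatetimeIndex(timestamps).floor("h")
    return baseline.hourly.reindex(hours).fillna(baseline.value).to_numpy()


@dataclass
class Bout:
    """A detected torpor bout (times refer to the sub-threshold span)."""

    start: pd.Timestamp
    end: pd.Timestamp
    duration_min: float
    bout_type: str | None = None
    mean_tmr: float = np.nan
    entry_time: pd.Timestamp | None = None
    arousal_time: pd.Timestamp | None = None
    mean_tskin: float = np.nan
    delta_tskin: float = np.nan
    tskin_confirmed: bool | None = None
    interior_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _candidate_runs(torpid: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    """Inclusive index runs of torpid candidates, merged across short gaps."""
    idx = np.flatnonzero(torpid)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > merge_gap + 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def _smoothed_slope_per_min(mr: np.ndarray, cadence_s: float) -> np.ndarray:
    """1-min boxcar smoothed MR slope in baseline units per minute."""
    win = max(1, int(round(60.0 / cadence_s)))
    kernel = np.ones(win) / win
    sm = np.convolve(mr, kernel, mode="same")
    return np.gradient(sm) * (60.0 / cadence_s)


def segment_bouts(
    mr_df: pd.DataFrame,
    torpid: np.ndarray,
    baseline: float,
    t_skin: pd.DataFrame | None = None,
    config: ClassifierConfig = ClassifierConfig(),
) -> tuple[list[Bout], np.ndarray, np.ndarray]:
    """Group torpid candidates into bouts and peel off entry/arousal phases.

    Returns (bouts, entry_mask, arousal_mask).  Entry/arousal samples are
    sub-threshold samples at bout edges whose smoothed 1-min slope exceeds
    ``slope_fraction_per_min`` × baseline; they are removed from bout
    interiors (so they never contribute to TMR) but the bout's start/end
    still span the full sub-threshold run.  ΔT_skin is the bout's mean
    T_skin minus the animal's euthermic (out-of-bout) mean.
    """
    ts = mr_df["timestamp"]
    mr = mr_df["mr_ml_g_h"].to_numpy(dtype=float)
    cadence = float(np.median(np.diff(ts.to_numpy()).astype("timedelta64[s]").astype(float))) if len(ts) > 1 else 10.0
    slope = _smoothed_slope_per_min(mr, cadence)
    thresh = config.slope_fraction_per_min * baseline

    entry_mask = np.zeros(len(mr), dtype=bool)
    arousal_mask = np.zeros(len(mr), dtype=bool)
    bouts: list[Bout] = []
    for i0, i1 in _candidate_runs(torpid, config.merge_gap_samples):
        # wall-clock duration: reference-air windows leave holes in the index,
        # so sample counts under-measure bouts that span them
        duration_min = ((ts.iloc[i1] - ts.iloc[i0]).total_seconds() + cadence) / 60.0
        if duration_min < config.min_bout_min:
            continue
        # steep falling edge at the start → ENTRY; steep rising edge → AROUSAL
        j = i0
        while j <= i1 and slope[j] < -thresh:
            j += 1
        k = i1
        while k >= j and slope[k] > thresh:
            k -= 1
        entry_mask[i0:j] = torpid[i0:j]
        arousal_mask[k + 1 : i1 + 1] = torpid[k + 1 : i1 + 1]
        interior = np.arange(j, k + 1)
        interior = interior[torpid[interior]] if len(interior) else interior
        arousal_time = ts.iloc[i1 + 1] if i1 + 1 < len(ts) else None
        bouts.append(
            Bout(
                start=ts.iloc[i0],
                end=ts.iloc[i1] + pd.Timedelta(seconds=cadence),
                duration_min=duration_min,
                entry_time=ts.iloc[i0],
                arousal_time=arousal_time,
                interior_idx=interior,
            )
        )

    if t_skin is not None and len(t_skin) and bouts:
        _annotate_tskin(bouts, t_skin)
    return bouts, entry_mask, arousal_mask


def _annotate_tskin(bouts: list[Bout], t_skin: pd.DataFrame) -> None:
    sts = pd.to_datetime(t_skin["timestamp"])
    svals = t_skin["t_skin_c"].to_numpy(dtype=float)
    in_any = np.zeros(len(sts), dtype=bool)
    per_bout = []
    for b in bouts:
        m = ((sts >= b.start) & (sts < b.end)).to_numpy()
        in_any |= m
        per_bout.append(m)
    if in_any.all():
        eu_ref = np.nan
    else:
        eu_ref = float(svals[~in_any].mean())
    for b, m in zip(bouts, per_bout):
        if m.any():
            b.mean_tskin = float(svals[m].mean())
            b.delta_tskin = b.mean_tskin - eu_ref


def classify_bout(bout: Bout, config: ClassifierConfig = ClassifierConfig()) -> str | None:
    """Duration (and optionally ΔT_skin) based bout taxonomy.

    Returns None for sub-5-min noise.  Extended bouts are flagged
    ``tskin_confirmed`` when |ΔT_skin| meets the 1.5 °C criterion; if T_skin
    is unavailable or the deviation is smaller, classification falls back to
    duration only with a warning.
    """
    if bout.duration_min < config.min_bout_min:
        return None
    if bout.duration_min < config.micro_max_min:
        bout.bout_type = MICRO
    elif bout.duration_min > config.multiday_min_h * 60.0:
        bout.bout_type = MULTIDAY
    else:
        bout.bout_type = EXTENDED
        if np.isnan(bout.delta_tskin):
            bout.tskin_confirmed = None
            warnings.warn(
                "T_skin unavailable; extended bout classified on duration only",
                stacklevel=2,
            )
        else:
            bout.tskin_confirmed = abs(bout.delta_tskin) >= config.tskin_delta_c
            if not bout.tskin_confirmed:
                warnings.warn(
                    f"extended bout at {bout.start}: |ΔT_skin| = "
                    f"{abs(bout.delta_tskin):.2f} °C below the "
                    f"{config.tskin_delta_c} °C criterion; kept on duration only",
                    stacklevel=2,
                )
    return bout.bout_type


def extract_tmr(
    mr_df: pd.DataFrame,
    bouts: Iterable[Bout],
    config: ClassifierConfig = ClassifierConfig(),
) -> None:
    """Attach per-bout mean TMR from the lowest 70 % of values per hour.

    Only bout-interior samples (entry/arousal already removed) are used; the
    quantile filter runs per clock hour within each bout with the floor
    rule, keeping at least one sample per hour.
    """
    mr = mr_df["mr_ml_g_h"].to_numpy(dtype=float)
    hours = mr_df["timestamp"].dt.floor("h").to_numpy()
    for b in bouts:
        if len(b.interior_idx) == 0:
            b.mean_tmr = np.nan
            continue
        vals = mr[b.interior_idx]
        keep = lowest_fraction_mask(vals, hours[b.interior_idx], config.tmr_quantile)
        b.mean_tmr = float(vals[keep].mean())


@dataclass
class StateSegmentation:
    """Per-sample labels, the RMR baseline and the bout table for one run."""

    labels: pd.Series
    rmr_baseline: RmrBaseline
    bouts: list[Bout]
    config: ClassifierConfig

    def bout_table(self, animal_id: str = "") -> pd.DataFrame:
        rows = [
            {
                "animal_id": animal_id,
                "date": b.entry_time.date(),
                "bout_type": b.bout_type,
                "start": b.start,
                "end": b.end,
                "duration_min": b.duration_min,
                "mean_tmr": b.mean_tmr,
                "delta_tskin_c": b.delta_tskin,
                "entry_time": b.entry_time,
                "arousal_time": b.arousal_time,
            }
            for b in self.bouts
            if b.bout_type is not None
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "animal_id", "date", "bout_type", "start", "end", "duration_min",
                "mean_tmr", "delta_tskin_c", "entry_time", "arousal_time",
            ],
        )


_BOUT_LABEL = {MICRO: MICRO_TORPOR, EXTENDED: EXTENDED_TORPOR, MULTIDAY: MULTIDAY_TORPOR}


def segment_run(
    mr_df: pd.DataFrame,
    windows: Sequence[RestingWindow],
    t_skin: pd.DataFrame | None = None,
    feeding_times: Sequence[dt.datetime] = (),
    config: ClassifierConfig = ClassifierConfig(),
) -> StateSegmentation:
    """Segment one run into the full physiological-state partition.

    ``mr_df`` needs columns ``timestamp`` and ``mr_ml_g_h`` at the raw
    cadence.  Every sample receives exactly one label; exclusion labels take
    precedence over transitions, which take precedence over bout states;
    remaining samples are REST inside a resting window and ACTIVE outside.
    Supra-threshold samples bridged inside a merged bout stay labelled REST
    so that every torpid-labelled sample truly sits at or below the
    threshold.
    """
    mr_df = mr_df.reset_index(drop=True)
    ts = mr_df["timestamp"]
    excl = apply_exclusions(ts, feeding_times, config)
    excluded = (excl["excluded_feeding"] | excl["excluded_stress"]).to_numpy()
    mr = mr_df["mr_ml_g_h"].to_numpy(dtype=float)

    in_window = np.zeros(len(mr_df), dtype=bool)
    for w in windows:
        in_window |= w.contains(ts)
    if not (in_window & ~excluded).any():
        raise ValueError("no usable resting-phase samples in this run")

    # Fixed-point iteration: the baseline is estimated on non-torpid samples
    # only.  Seed it with a high quantile of the resting-phase MR so that
    # torpor-heavy days (where the hourly lowest-50% of ALL samples would sit
    # near TMR) still start above the euthermic floor; overshooting is safe
    # because an over-wide torpid mask is simply pruned on the next pass.
    b0 = float(np.quantile(mr[in_window & ~excluded], 0.9))
    torpid = detect_torpor(mr, b0, config.torpor_fraction)
    baseline = None
    for _ in range(config.max_baseline_iter):
        baseline = extract_rmr(mr_df, windows, excluded=excluded, torpid=torpid, config=config)
        new_torpid = detect_torpor(
            mr, _per_sample_baseline(baseline, ts, config), config.torpor_fraction
        )
        if np.array_equal(new_torpid, torpid):
            break
        torpid = new_torpid
    torpid &= ~excluded

    bouts, entry_mask, arousal_mask = segment_bouts(
        mr_df, torpid, baseline.value, t_skin=t_skin, config=config
    )
    for b in bouts:
        classify_bout(b, config)
    bouts = [b for b in bouts if b.bout_type is not None]
    extract_tmr(mr_df, bouts, config)

    labels = np.where(in_window, REST, ACTIVE).astype(object)
    for b in bouts:
        labels[b.interior_idx] = _BOUT_LABEL[b.bout_type]
    labels[entry_mask] = ENTRY
    labels[arousal_mask] = AROUSAL
    labels[excl["excluded_stress"].to_numpy()] = EXCLUDED_STRESS
    labels[excl["excluded_feeding"].to_numpy()] = EXCLUDED_FEEDING
    return StateSegmentation(
        labels=pd.Series(labels, index=mr_df.index, name="state"),
        rmr_baseline=baseline,
        bouts=bouts,
        config=config,
    )


def daily_metrics(bout_table: pd.DataFrame) -> pd.DataFrame:
    """Per animal-day bout metrics; a bout belongs to its entry-time day.

    Columns: micro_count, micro_mean_duration_min, extended_total_min,
    total_torpid_min.  The per-animal mean daily micro frequency is the mean
    of micro_count across that animal's observed days.
    """
    if bout_table.empty:
        return pd.DataFrame(
            columns=["animal_id", "date", "micro_count", "micro_mean_duration_min",
                     "extended_total_min", "total_torpid_min"]
        )
    df = bout_table.copy()
    rows = []
    for (animal, day), grp in df.groupby(["animal_id", "date"]):
        micro = grp[grp["bout_type"] == MICRO]
        ext = grp[grp["bout_type"].isin([EXTENDED, MULTIDAY])]
        rows.append(
            {
                "animal_id": animal,
                "date": day,
                "micro_count": len(micro),
                "micro_mean_duration_min": micro["duration_min"].mean() if len(micro) else np.nan,
                "extended_total_min": float(ext["duration_min"].sum()),
                "total_torpid_min": float(grp["duration_min"].sum()),
            }
        )
    return pd.DataFrame(rows)


def mean_daily_micro_frequency(daily: pd.DataFrame) -> pd.Series:
    """Average micro-torpor bouts per day, per animal."""
    return daily.groupby("animal_id")["micro_count"].mean()


def classify_strategy(day_bouts: pd.DataFrame) -> str:
    """Daily torpor strategy from one animal-day's classified bout table."""
    if day_bouts.empty:
        return EUTHERMIC
    types = set(day_bouts["bout_type"])
    has_micro = MICRO in types
    has_ext = bool(types & {EXTENDED, MULTIDAY})
    if has_micro and has_ext:
        return MICRO_PLUS_EXTENDED
    if has_micro:
        return MICRO_ONLY
    return EXTENDED_ONLY


def strategy_table(
    bout_table: pd.DataFrame,
    animal_days: Iterable[tuple[str, dt.date]],
) -> pd.DataFrame:
    """Strategy label for every observed animal-day.

    ``animal_days`` enumerates the days each animal was actually measured,
    so days without any bout are reported as EUTHERMIC rather than dropped.
    """
    rows = []
    for animal, day in animal_days:
        if bout_table.empty:
            sub = bout_table
        else:
            sub = bout_table[
                (bout_table["animal_id"] == animal) & (bout_table["date"] == day)
            ]
        strat = classify_strategy(sub)
        rows.append(
            {
                "animal_id": animal,
                "date": day,
                "strategy": strat,
                "micro_count": int((sub["bout_type"] == MICRO).sum()) if len(sub) else 0,
                "multiday": bool((sub["bout_type"] == MULTIDAY).any()) if len(sub) else False,
            }
        )
    return pd.DataFrame(rows)
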