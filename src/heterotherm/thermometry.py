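"""Transmitter calibration, skin-temperature series and Tₐ-bin scaffolding.

Temperature-sensitive transmitters are calibrated in a water bath against
reference temperatures; a second-order polynomial (accepted only at
R² ≥ 0.99) maps the raw signal to skin temperature.  Ambient temperature and
relative humidity from in-chamber loggers (5-min cadence) are matched to the
metabolic samples by nearest timestamp, and per-animal state means are
allocated to integer Tₐ bins for all between-roost metabolic comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Minimum acceptable calibration fit quality.
R2_MIN = 0.99

#: Temperature span (°C) a calibration point set must cover.
MIN_CAL_SPAN_C = 20.0

#: Environment record considered matched if within this many seconds.
ENV_MATCH_TOLERANCE_S = 300.0

OVERLAP_WINDOWS = {"28-30": (28, 30), "31-34": (31, 34)}


class CalibrationError(ValueError):
    """Calibration points are insufficient or the fit is below standard."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Quadratic raw-signal → temperature map (numpy polyval order)."""

    coefficients: tuple[float, float, float]  # highest power first
    r_squared: float
    signal_range: tuple[float, float]
    temp_range: tuple[float, float]
    transmitter_id: str = ""

    def __call__(self, raw: np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(raw, dtype=float))


def fit_calibration(
    points: Sequence[tuple[float, float]],
    transmitter_id: str = "",
    r2_min: float = R2_MIN,
) -> CalibrationCurve:
    """Least-squares quadratic through (raw_signal, reference_temp) pairs.

    Requires at least 4 points spanning at least 20 °C; rejects fits whose
    R² falls below ``r2_min``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 4:
        raise CalibrationError("need at least 4 calibration points")
    raw, temp = pts[:, 0], pts[:, 1]
    if temp.max() - temp.min() < MIN_CAL_SPAN_C:
        raise CalibrationError(
            f"calibration points span {temp.max() - temp.min():.1f} °C; "
            f"need ≥ {MIN_CAL_SPAN_C} °C"
        )
    coeffs = np.polyfit(raw, temp, 2)
    resid = temp - np.polyval(coeffs, raw)
    ss_tot = float(np.sum((temp - temp.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    if r2 < r2_min:
        raise CalibrationError(
            f"transmitter {transmitter_id or '?'}: calibration R² = {r2:.4f} "
            f"< {r2_min}; rejected"
        )
    return CalibrationCurve(
        coefficients=tuple(coeffs),
        r_squared=r2,
        signal_range=(float(raw.min()), float(raw.max())),
        temp_range=(float(temp.min()), float(temp.max())),
        transmitter_id=transmitter_id,
    )


def apply_calibration(
    curve: CalibrationCurve, raw: pd.Series, timestamps: pd.Series | None = None
) -> pd.DataFrame:
    """Evaluate the calibration polynomial per sample.

    Raw values beyond the calibrated signal range by more than 10 % of the
    range trigger an extrapolation warning but are still converted.
    Returns a frame with columns ``timestamp`` (if given) and ``t_skin_c``.
    """
    vals = np.asarray(raw, dtype=float)
    lo, hi = curve.signal_range
    margin = 0.10 * (hi - lo)
    if np.any(vals < lo - margin) or np.any(vals > hi + margin):
        warnings.warn(
            f"raw signal outside calibrated range [{lo}, {hi}] by more than "
            "10%; extrapolated temperatures are unreliable",
            stacklevel=2,
        )
    out = pd.DataFrame({"t_skin_c": curve(vals)})
    if timestamps is not None:
        out.insert(0, "timestamp", np.asarray(timestamps))
    return out


def read_environment(path) -> pd.DataFrame:
    """Read an ambient logger CSV with columns timestamp, t_a_c, rh_pct."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = {"timestamp", "t_a_c", "rh_pct"} - set(df.columns)
    if missing:
        raise ValueError(f"environment file missing columns: {sorted(missing)}")
    return df


def align_environment(
    env: pd.DataFrame,
    trace: pd.DataFrame,
    tolerance_s: float = ENV_MATCH_TOLERANCE_S,
) -> pd.DataFrame:
    """Annotate each metabolic sample with the nearest-in-time Tₐ/RHₐ.

    Nearest-neighbour matching (no interpolation) within ``tolerance_s``;
    unmatched samples keep NaN and are flagged ``env_matched = False``.
    """
    if env["timestamp"].max() < trace["timestamp"].min() or env[
        "timestamp"
    ].min() > trace["timestamp"].max():
        raise ValueError("environment log and trace do not overlap in time")
    merged = pd.merge_asof(
        trace.sort_values("timestamp"),
        env.sort_values("timestamp")[["timestamp", "t_a_c", "rh_pct"]],
        on="timestamp",
        direction="nearest",
        tolerance=pd.Timedelta(seconds=tolerance_s),
    )
    merged["env_matched"] = merged["t_a_c"].notna()
    return merged


def round_half_up(x) -> np.ndarray:
    """Round to nearest integer with .5 going up (np.round rounds to even)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


@dataclass
class TempBinTable:
    """Per-(animal, state, integer Tₐ bin) mean MR, pseudo-replication-safe.

    Each animal contributes at most one value per state and bin; bins are
    retained only where at least ``min_animals`` animals were measured in a
    roosting condition.
    """

    table: pd.DataFrame  # columns: animal_id, site_season, state, ta_bin, mr
    min_animals: int = 3

    def animal_counts(self) -> pd.DataFrame:
        return (
            self.table.groupby(["site_season", "state", "ta_bin"])["animal_id"]
            .nunique()
            .rename("n_animals")
            .reset_index()
        )

    def overlap_subset(self, window: str) -> pd.DataFrame:
        """Rows in one of the shared-Tₐ comparison windows ('28-30', '31-34')."""
        lo, hi = OVERLAP_WINDOWS[window]
        return self.table[self.table["ta_bin"].between(lo, hi)].reset_index(drop=True)


def build_temp_bins(
    samples: pd.DataFrame, min_animals: int = 3
) -> TempBinTable:
    """Allocate per-animal state means to integer Tₐ bins.

    ``samples`` needs columns animal_id, site_season, state, t_a_c, mr.
    Bins are the half-up rounding of Tₐ; within each (animal, state, bin) the
    mean MR is taken so each animal contributes a single value, and bins with
    fewer than ``min_animals`` animals in a roosting condition are dropped.
    """
    if samples.empty:
        return TempBinTable(
            table=pd.DataFrame(
                columns=["animal_id", "site_season", "state", "ta_bin", "mr"]
            ),
            min_animals=min_animals,
        )
    df = samples.copy()
    df["ta_bin"] = round_half_up(df["t_a_c"])
    per_animal = (
        df.groupby(["animal_id", "site_season", "state", "ta_bin"], as_index=False)[
            "mr"
        ].mean()
    )
    counts = per_animal.groupby(["site_season", "state", "ta_bin"])[
        "animal_id"
    ].transform("nunique")
    kept = per_animal[counts >= min_animals].reset_index(drop=True)
    return TempBinTable(table=kept, min_animals=min_animals)
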