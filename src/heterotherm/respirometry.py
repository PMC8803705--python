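"""Open-flow respirometry trace processing.

Raw analyzer output is a 10-s cadence series of excurrent O2 fractions that
alternates between ~55 min of chamber ("sample") air and ~5 min of outside
("reference") air.  The reference segments anchor a piecewise-linear baseline
that removes electrochemical-sensor drift; the corrected depletion is then
converted to an oxygen-consumption rate (V̇O2, ml O2 h⁻¹ at STPD) with the
pull-mode, water-scrubbed, CO2-present flow equation

    V̇O2 = FR · (FiO2 − FeO2) / (1 − FeO2 · (1 − RQ))

where FR is the mass-flow rate (here expressed in ml h⁻¹ at STPD), FiO2 and
FeO2 the incurrent and excurrent dry O2 fractions and RQ the assumed
respiratory quotient.  Dividing by body mass yields the mass-specific
metabolic rate in ml O2 g⁻¹ h⁻¹ used by every downstream analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

SAMPLE = "S"
REFERENCE = "R"

#: Plausible range for a dry-air O2 fraction from a working sensor.
O2_FRACTION_RANGE = (0.15, 0.25)

#: Seconds of each reference segment discarded at both ends as washout.
REFERENCE_WASHOUT_S = 30.0


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class TraceDataError(ValueError):
    """The file parses but violates a trace invariant."""


@dataclass(frozen=True)
class RunMetadata:
    """Per-run configuration accompanying a raw trace file.

    ``body_mass_g`` is the mean of the pre- and post-run masses, the best
    available estimate of average mass during a measurement.
    """

    flow_lph: float
    bm_pre_g: float
    bm_post_g: float
    animal_id: str
    site_season: str = "cave_dry"
    fio2: float = 0.2095
    rq: float = 0.85
    chamber_id: str = ""

    def __post_init__(self) -> None:
        if self.flow_lph <= 0:
            raise ValueError("flow_lph must be positive")
        if not 0.7 <= self.rq <= 1.0:
            raise ValueError(f"rq must lie in [0.7, 1.0], got {self.rq}")

    @property
    def body_mass_g(self) -> float:
        return 0.5 * (self.bm_pre_g + self.bm_post_g)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "RunMetadata":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in mapping.items() if k in known})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunMetadata":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))


@dataclass
class RawO2Trace:
    """A validated raw O2-fraction trace with sample/reference labels."""

    data: pd.DataFrame  # columns: timestamp, o2_fraction, segment
    flow_lph: float
    animal_id: str = ""
    chamber_id: str = ""
    gaps: list = field(default_factory=list)
    drift_corrected: bool = False

    @property
    def timestamps(self) -> pd.Series:
        return self.data["timestamp"]

    @property
    def o2_fraction(self) -> pd.Series:
        return self.data["o2_fraction"]

    def reference_segments(self) -> list[pd.DataFrame]:
        """Contiguous runs of REFERENCE rows, in time order."""
        seg = self.data["segment"].to_numpy()
        change = np.flatnonzero(np.diff((seg == REFERENCE).astype(int)) != 0) + 1
        blocks = np.split(np.arange(len(seg)), change)
        return [self.data.iloc[b] for b in blocks if len(b) and seg[b[0]] == REFERENCE]


@dataclass
class MetabolicTrace:
    """V̇O2 (and optionally mass-specific MR) at the raw 10-s cadence."""

    data: pd.DataFrame  # columns: timestamp, vo2_ml_h [, mr_ml_g_h]
    body_mass_g: float | None = None
    rq: float = 0.85
    n_clipped: int = 0

    @property
    def mr(self) -> pd.Series:
        if "mr_ml_g_h" not in self.data:
            raise AttributeError("mass-specific MR not yet computed")
        return self.data["mr_ml_g_h"]


def _validate_raw(df: pd.DataFrame) -> None:
    required = {"timestamp", "o2_fraction", "segment"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    ts = df["timestamp"]
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise TraceDataError("timestamps must be strictly increasing")
    lo, hi = O2_FRACTION_RANGE
    bad = ~df["o2_fraction"].between(lo, hi, inclusive="neither")
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise TraceDataError(
            f"o2_fraction outside ({lo}, {hi}) at row {i}: {df['o2_fraction'].iloc[i]}"
        )
    unknown = ~df["segment"].isin([SAMPLE, REFERENCE])
    if unknown.any():
        raise SchemaError("segment labels must be 'S' or 'R'")


def read_trace(path: str | Path, metadata: RunMetadata) -> RawO2Trace:
    """Read and validate one raw analyzer CSV.

    Gaps longer than twice the median cadence are recorded in ``trace.gaps``
    as (time-before-gap, gap-length-seconds) pairs, not filled.
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    _validate_raw(df)
    dt = df["timestamp"].diff().dt.total_seconds().to_numpy()[1:]
    cadence = float(np.median(dt)) if len(dt) else 10.0
    gaps = [
        (df["timestamp"].iloc[i], float(dt[i]))
        for i in np.flatnonzero(dt > 2 * cadence)
    ]
    return RawO2Trace(
        data=df.reset_index(drop=True),
        flow_lph=metadata.flow_lph,
        animal_id=metadata.animal_id,
        chamber_id=metadata.chamber_id,
        gaps=gaps,
    )


def write_trace(trace: RawO2Trace, path: str | Path) -> None:
    """Write a trace back to the raw CSV layout (round-trips read_trace)."""
    out = trace.data.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, float_format="%.6f")


def drift_correct(trace: RawO2Trace, fio2: float = 0.2095) -> RawO2Trace:
    """Remove sensor drift using the interleaved reference-air segments.

    Each reference segment (first and last 30 s dropped as washout) is
    summarised by its median O2 fraction, anchored at the segment's temporal
    midpoint.  A piecewise-linear baseline through the anchors — held
    constant before the first and after the last — estimates what the sensor
    reads for air of fraction ``fio2``; sample rows are shifted by
    ``fio2 − baseline`` and reference rows are dropped.  Applying the
    correction to an already-corrected trace is a no-op.
    """
    if trace.drift_corrected:
        return trace
    refs = trace.reference_segments()
    if not refs:
        raise TraceDataError(
            "no reference segments found; apply a manual baseline instead"
        )
    t0 = trace.data["timestamp"].iloc[0]
    anchor_t, anchor_v = [], []
    for seg in refs:
        ts = (seg["timestamp"] - t0).dt.total_seconds().to_numpy()
        keep = (ts >= ts[0] + REFERENCE_WASHOUT_S) & (ts <= ts[-1] - REFERENCE_WASHOUT_S)
        vals = seg["o2_fraction"].to_numpy()[keep] if keep.any() else seg["o2_fraction"].to_numpy()
        anchor_t.append(0.5 * (ts[0] + ts[-1]))
        anchor_v.append(float(np.median(vals)))
    samples = trace.data[trace.data["segment"] == SAMPLE].copy()
    st = (samples["timestamp"] - t0).dt.total_seconds().to_numpy()
    baseline = np.interp(st, anchor_t, anchor_v)  # constant beyond the ends
    samples["o2_fraction"] = samples["o2_fraction"].to_numpy() + (fio2 - baseline)
    return replace(
        trace, data=samples.reset_index(drop=True), drift_corrected=True
    )


def compute_vo2(trace: RawO2Trace, fio2: float = 0.2095, rq: float = 0.85) -> MetabolicTrace:
    """Convert a drift-corrected trace to V̇O2 (ml O2 h⁻¹, STPD).

    Uses the pull-mode equation for dried sample air with CO2 left in the
    stream and flow measured downstream of the chamber.  Transient negative
    rates (noise around zero depletion) are clipped to 0 and counted; more
    than 5 % clipped raises a warning.
    """
    if not 0.7 <= rq <= 1.0:
        raise ValueError(f"rq must lie in [0.7, 1.0], got {rq}")
    feo2 = trace.o2_fraction.to_numpy(dtype=float)
    if np.mean(feo2 >= fio2) > 0.5:
        warnings.warn(
            "fio2 does not exceed the excurrent fraction over most of the "
            "trace; check the incurrent-fraction configuration",
            stacklevel=2,
        )
    fr_ml = trace.flow_lph * 1000.0
    vo2 = fr_ml * (fio2 - feo2) / (1.0 - feo2 * (1.0 - rq))
    n_clipped = int(np.sum(vo2 < 0))
    if n_clipped > 0.05 * len(vo2):
        warnings.warn(
            f"{n_clipped}/{len(vo2)} negative V̇O2 values clipped to 0; "
            "drift correction may be inadequate",
            stacklevel=2,
        )
    out = pd.DataFrame(
        {"timestamp": trace.timestamps.to_numpy(), "vo2_ml_h": np.clip(vo2, 0.0, None)}
    )
    return MetabolicTrace(data=out, rq=rq, n_clipped=n_clipped)


def mass_specific_mr(trace: MetabolicTrace, bm: float) -> MetabolicTrace:
    """Attach mass-specific MR (ml O2 g⁻¹ h⁻¹) computed as V̇O2 / bm."""
    if bm <= 0:
        raise ValueError(f"body mass must be positive, got {bm}")
    data = trace.data.copy()
    data["mr_ml_g_h"] = data["vo2_ml_h"] / bm
    return replace(trace, data=data, body_mass_g=bm)


def per_minute_series(trace: MetabolicTrace, column: str = "mr_ml_g_h") -> pd.Series:
    """Average the 10-s samples within each clock minute.

    Returns a series indexed by minute start covering the trace span; minutes
    containing no samples are NaN.
    """
    if column not in trace.data:
        raise KeyError(f"column {column!r} not present; run mass_specific_mr first")
    s = trace.data.set_index("timestamp")[column]
    return s.resample("1min").mean()


def process_run(
    path: str | Path, metadata: RunMetadata
) -> tuple[RawO2Trace, MetabolicTrace]:
    """Full raw-file pipeline: read, drift-correct, V̇O2, mass-specific MR."""
    raw = read_trace(path, metadata)
    corrected = drift_correct(raw, fio2=metadata.fio2)
    mt = compute_vo2(corrected, fio2=metadata.fio2, rq=metadata.rq)
    return corrected, mass_specific_mr(mt, metadata.body_mass_g)
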