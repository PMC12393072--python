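"""Turn raw per-second sensor streams into per-sensor odor-emission features.

The measurement logic of the device is: record one reading per second over a
100-s phase, take the median of every 10-s window, and fit an ordinary
least-squares line through the window medians.  The slope of that line
(a.u./s) is the *signal amplification rate*.  In survey mode the slope of a
room-air phase is subtracted from the slope of a sample-air phase, so the net
slope isolates the odor emitted by the sample from chamber drift.  In
prototype mode each acquisition cycle is reset (300 s of charcoal-filtered
air), sampling (100 s of fruit air) and rest (200 s); the first 70 sampling
readings are discarded to let the signal stabilise after the air switch and
the last 30 are retained for analysis.

Median-then-slope is deliberately robust: a single transient spike inside a
10-s window cannot move that window's median, and the linear fit removes the
slow thermal drift common to MOS sensors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDesignError,
    InsufficientDataError,
    PhaseSequenceError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: fraction of seconds that may be missing from a phase before it is an error
MAX_MISSING_FRACTION = 0.05

#: columns that are never sensor channels in a stream frame
STREAM_META_COLUMNS = (
    "time_s", "phase", "fruit_id", "group", "day", "replicate",
    "temp_c", "rh_pct",
)


def sensor_columns(stream: pd.DataFrame) -> list[str]:
    """Names of the sensor-channel columns of a stream frame."""
    return [c for c in stream.columns if c not in STREAM_META_COLUMNS]


@dataclass(frozen=True)
class PhaseSchedule:
    """Durations (s) of the acquisition phases.

    Two presets cover the two operating modes: ``PhaseSchedule.prototype()``
    is the relay-driven reset/sampling/rest cycle of the deployed device and
    ``PhaseSchedule.survey()`` is the paired room-air/sample-air cycle of the
    13-sensor sensitivity survey.  Both are the same code path downstream.
    """

    reset_s: int = 300
    sampling_s: int = 100
    rest_s: int = 200
    survey_room_air_s: int = 100
    survey_sample_s: int = 100
    mode: str = "prototype"

    def __post_init__(self) -> None:
        for name in ("reset_s", "sampling_s", "rest_s",
                     "survey_room_air_s", "survey_sample_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.mode not in ("prototype", "survey"):
            raise ValidationError(f"unknown schedule mode {self.mode!r}")

    @classmethod
    def prototype(cls) -> "PhaseSchedule":
        return cls(mode="prototype")

    @classmethod
    def survey(cls) -> "PhaseSchedule":
        return cls(mode="survey")

    @property
    def phases(self) -> tuple[tuple[str, int], ...]:
        """Ordered (phase name, duration) pairs for one cycle."""
        if self.mode == "survey":
            return (("room_air", self.survey_room_air_s),
                    ("sample_air", self.survey_sample_s))
        return (("reset", self.reset_s),
                ("sampling", self.sampling_s),
                ("rest", self.rest_s))

    @property
    def cycle_s(self) -> int:
        return sum(d for _, d in self.phases)


@dataclass
class MeasurementCycle:
    """One acquisition unit: per-phase sub-streams of a single cycle."""

    cycle_id: int
    phases: dict[str, pd.DataFrame]
    metadata: dict = field(default_factory=dict)

    def phase(self, name: str) -> pd.DataFrame:
        try:
            return self.phases[name]
        except KeyError:
            raise ValidationError(
                f"cycle {self.cycle_id} has no phase {name!r}") from None


@dataclass(frozen=True)
class SlopeFeature:
    """Per-sensor signal slope (a.u./s) in a given context."""

    sensor: str
    slope: float
    context: str  # room_air | sample_air | net

    def __post_init__(self) -> None:
        if self.context not in ("room_air", "sample_air", "net"):
            raise ValidationError(f"unknown slope context {self.context!r}")


def _repair_phase(block: pd.DataFrame, duration: int, t0: float,
                  where: str) -> pd.DataFrame:
    """Reindex a phase block onto its full 1-s grid, interpolating up to
    MAX_MISSING_FRACTION dropped seconds (serial links lose lines)."""
    grid = np.arange(duration, dtype=float) + t0
    missing = duration - len(block)
    if missing < 0:
        raise PhaseSequenceError(
            f"{where}: phase has {len(block)} samples, schedule allows {duration}")
    if missing == 0:
        return block.reset_index(drop=True)
    if missing > MAX_MISSING_FRACTION * duration:
        raise InsufficientDataError(
            f"{where}: {missing} of {duration} seconds missing "
            f"(> {MAX_MISSING_FRACTION:.0%} tolerance)")
    logger.warning("%s: interpolating %d missing second(s)", where, missing)
    indexed = block.set_index("time_s").reindex(grid)
    numeric = indexed.select_dtypes("number").interpolate(
        method="index", limit_direction="both")
    repaired = indexed.copy()
    repaired[numeric.columns] = numeric
    for col in repaired.columns:
        if repaired[col].dtype == object:
            repaired[col] = repaired[col].ffill().bfill()
    return repaired.reset_index(names="time_s")


def segment_cycles(stream: pd.DataFrame,
                   schedule: PhaseSchedule) -> list[MeasurementCycle]:
    """Split a raw stream into complete measurement cycles.

    Readings are assigned to consecutive runs of their phase label; runs must
    follow the schedule's phase grammar.  A trailing partial cycle is dropped
    with a warning so that every returned cycle is complete.
    """
    if stream.empty:
        return []
    phase_names = [p for p, _ in schedule.phases]
    runs: list[tuple[str, pd.DataFrame]] = []
    run_id = (stream["phase"] != stream["phase"].shift()).cumsum()
    for _, block in stream.groupby(run_id, sort=False):
        runs.append((block["phase"].iloc[0], block))

    cycles: list[MeasurementCycle] = []
    i = 0
    n_assigned = 0
    while i + len(phase_names) <= len(runs):
        window = runs[i:i + len(phase_names)]
        got = [p for p, _ in window]
        if got != phase_names:
            t_bad = window[0][1]["time_s"].iloc[0]
            raise PhaseSequenceError(
                f"phase sequence {got} at time_s={t_bad} does not match "
                f"schedule {phase_names}")
        cid = len(cycles)
        phases = {}
        for (pname, block), (_, dur) in zip(window, schedule.phases):
            phases[pname] = _repair_phase(
                block, dur, float(block["time_s"].iloc[0]),
                where=f"cycle {cid} phase {pname}")
            n_assigned += len(block)
        cycles.append(MeasurementCycle(cycle_id=cid, phases=phases))
        i += len(phase_names)
    # trailing runs may only be a partial cycle: a prefix of the phase
    # grammar with complete durations except possibly the last run
    trailing = runs[i:]
    if trailing:
        got = [p for p, _ in trailing]
        if got != phase_names[:len(got)]:
            t_bad = trailing[0][1]["time_s"].iloc[0]
            raise PhaseSequenceError(
                f"trailing phase sequence {got} at time_s={t_bad} is not a "
                f"prefix of schedule {phase_names}")
        for k, (pname, block) in enumerate(trailing):
            dur = dict(schedule.phases)[pname]
            if len(block) > dur or (k < len(trailing) - 1
                                    and dur - len(block)
                                    > MAX_MISSING_FRACTION * dur):
                t_bad = block["time_s"].iloc[0]
                raise PhaseSequenceError(
                    f"phase {pname!r} at time_s={t_bad} has {len(block)} "
                    f"samples, schedule expects {dur}")
    dropped = sum(len(b) for _, b in trailing)
    if dropped:
        logger.warning("dropping trailing partial cycle (%d samples)", dropped)
    if n_assigned + dropped != len(stream):
        raise PhaseSequenceError("sample conservation violated during segmentation")
    return cycles


def window_medians(series: np.ndarray | pd.Series,
                   window_s: int = 10) -> list[tuple[float, float]]:
    """Median of every ``window_s``-second window of a 1-Hz series.

    Windows are half-open ``[k*w, (k+1)*w)`` over the 0-based sample index; a
    trailing remainder shorter than one window is an error upstream (phase
    repair guarantees exact lengths here).  Returns ``(midpoint_s, median)``
    pairs with midpoints at ``(k + 0.5) * w`` so a later regression is in
    a.u. per second.
    """
    values = np.asarray(series, dtype=float)
    if window_s <= 0:
        raise ValidationError("window_s must be > 0")
    if len(values) < window_s:
        raise InsufficientDataError(
            f"series of {len(values)} samples is shorter than one "
            f"{window_s}-s window")
    if len(values) % window_s != 0:
        raise ValidationError(
            f"series length {len(values)} is not a multiple of window_s={window_s}")
    n_win = len(values) // window_s
    meds = np.median(values.reshape(n_win, window_s), axis=1)
    mids = (np.arange(n_win) + 0.5) * window_s
    return list(zip(mids.tolist(), meds.tolist()))


def ols_slope(points: list[tuple[float, float]] | np.ndarray) -> float:
    """Ordinary least-squares slope of value on time; intercept discarded."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise InsufficientDataError("need >= 2 (time, value) points")
    t, y = pts[:, 0], pts[:, 1]
    if np.ptp(t) == 0:
        raise DegenerateDesignError("all time values equal; slope undefined")
    return float(stats.linregress(t, y).slope)


def phase_slope(block: pd.DataFrame, sensor: str, context: str,
                window_s: int = 10) -> SlopeFeature:
    """Windowed-median OLS slope of one sensor over one phase block."""
    pts = window_medians(block[sensor].to_numpy(), window_s=window_s)
    if len(pts) < 2:
        raise InsufficientDataError(
            f"phase too short for a slope ({len(pts)} median point(s))")
    return SlopeFeature(sensor=sensor, slope=ols_slope(pts), context=context)


def net_odor_slope(sample: SlopeFeature, room: SlopeFeature) -> SlopeFeature:
    """Net odor emission of the sample: sample-air slope minus room-air slope."""
    if sample.sensor != room.sensor:
        raise ValidationError(
            f"sensor mismatch: {sample.sensor!r} vs {room.sensor!r}")
    if sample.context != "sample_air" or room.context != "room_air":
        raise ValidationError(
            "net slope needs a sample_air and a room_air feature")
    return SlopeFeature(sensor=sample.sensor,
                        slope=sample.slope - room.slope, context="net")


def trim_sampling(readings: pd.DataFrame | np.ndarray,
                  keep_last: int = 30):
    """Retain the last ``keep_last`` readings of a sampling phase.

    The early part of the sampling phase is contaminated by the transient
    that follows switching from control to sample air; the device discards
    the first 70 of 100 readings and keeps the final 30.
    """
    n = len(readings)
    if n < keep_last:
        raise InsufficientDataError(
            f"{n} readings < keep_last={keep_last}")
    if isinstance(readings, pd.DataFrame):
        return readings.iloc[n - keep_last:]
    return np.asarray(readings)[n - keep_last:]


def extract_survey_features(stream: pd.DataFrame,
                            schedule: PhaseSchedule | None = None,
                            window_s: int = 10) -> pd.DataFrame:
    """Per-sensor net slopes for every survey cycle of a stream.

    Returns the long feature table
    ``cycle_id,fruit_id,group,day,sensor,slope_room,slope_sample,slope_net``.
    """
    schedule = schedule or PhaseSchedule.survey()
    if schedule.mode != "survey":
        raise ValidationError("extract_survey_features needs a survey schedule")
    rows = []
    for cycle in segment_cycles(stream, schedule):
        room = cycle.phase("room_air")
        samp = cycle.phase("sample_air")
        meta = {k: (room[k].iloc[0] if k in room.columns else None)
                for k in ("fruit_id", "group", "day")}
        for sensor in sensor_columns(room):
            f_room = phase_slope(room, sensor, "room_air", window_s)
            f_samp = phase_slope(samp, sensor, "sample_air", window_s)
            net = net_odor_slope(f_samp, f_room)
            rows.append({"cycle_id": cycle.cycle_id, **meta, "sensor": sensor,
                         "slope_room": f_room.slope,
                         "slope_sample": f_samp.slope,
                         "slope_net": net.slope})
    return pd.DataFrame(rows)
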